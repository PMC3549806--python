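"""Exception hierarchy for the pairpssm toolkit."""


class PairPssmError(Exception):
    """Base class for all toolkit errors."""


class ChainNotFound(PairPssmError):
    """Requested chain id is absent from the structure."""


class EmptyChain(PairPssmError):
    """A chain contains no standard polymer residues."""


class AnnotationConflict(PairPssmError):
    """Domain annotations overlap on a single chain."""


class FormatError(PairPssmError):
    """An input table does not have the required shape or labels."""


class ValidationError(PairPssmError):
    """An input parsed but violates a semantic constraint."""


class EmptyTemplate(PairPssmError):
    """The template row of an alignment contains only gaps."""


class InsufficientPairs(UserWarning):
    """Only the template pair survived row pairing; profile is prior-only."""


class DegenerateWeights(PairPssmError):
    """Pseudocount mixing weights alpha + beta are zero."""


class BuildError(PairPssmError):
    """A contact position could not be mapped onto the profile."""


class NormalizationUndefined(PairPssmError):
    """Template self-energy is not positive; normalized energy undefined."""


class UndefinedPC(PairPssmError):
    """Pair coverage is undefined because a contact map is empty."""


class EmptyCluster(PairPssmError):
    """Representative selection called on an empty cluster."""


class FPUndefined(PairPssmError):
    """False-positive rate undefined because the hit list has no negatives."""


class NoEvaluableTemplates(PairPssmError):
    """Mean metrics requested over an empty per-template list."""


class EmptyClass(PairPssmError):
    """An error-rate sweep needs at least one score in each class."""


class InfeasibleSpec(PairPssmError):
    """A fixture specification cannot be realised geometrically."""
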