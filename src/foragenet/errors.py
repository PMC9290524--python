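"""Named exceptions shared across the pipeline stages."""


class ForagenetError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(ForagenetError, ValueError):
    """A configuration value violates its documented precondition."""


class ConstantGeneError(ForagenetError, ValueError):
    """A gene has zero variance across samples; correlations are undefined."""


class DegenerateModuleError(ForagenetError, ValueError):
    """A gene set carries no variance; its eigengene is undefined."""


class ConstantFactorError(ForagenetError, ValueError):
    """An environmental factor is constant; correlation with it is undefined."""


class RankDeficientDesignError(ForagenetError, ValueError):
    """The regression design matrix is rank deficient.

    Usually means two factors are (nearly) collinear; prune with
    :func:`foragenet.interplay.drop_collinear_factors` first.
    """


class InvalidReferenceError(ForagenetError, ValueError):
    """An rRNA reference sequence violates a precondition (e.g. too short)."""
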