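"""Exception and warning types used across the package."""


class FahpError(Exception):
    """Base class for all errors raised by preterm_fahp."""


class ScaleError(FahpError):
    """Invalid linguistic scale, or a label not found in a scale."""


class MatrixError(FahpError):
    """A fuzzy pairwise-comparison matrix violates a structural invariant."""


class DegenerateWeightsError(FahpError):
    """Extent analysis produced all-zero minimum possibility degrees."""


class ConsistencyError(FahpError):
    """A comparison matrix failed the CR < 0.1 consistency screen."""


class HierarchyError(FahpError):
    """Invalid risk hierarchy (weight sums, duplicate names, missing parts)."""


class JudgmentError(FahpError):
    """Invalid or incomplete expert case judgments."""


class ConfigError(FahpError):
    """Malformed configuration or data file."""


class ZeroWeightWarning(UserWarning):
    """Extent analysis assigned weight zero to one or more criteria.

    This is a known pathology of the extent-analysis method: when the
    fuzzy synthetic extent of a weak criterion does not overlap the
    strongest one, its minimum degree of possibility -- and hence its
    normalized weight -- collapses to exactly zero.
    """


class ZeroJudgmentWarning(UserWarning):
    """A judgment value of zero was floored before a geometric mean.

    A single zero would annihilate the geometric-mean consensus of an
    entire panel, so zeros are replaced by a small positive floor.
    """
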