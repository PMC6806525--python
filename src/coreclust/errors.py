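"""Exception hierarchy shared across the package."""


class CoreclustError(Exception):
    """Base class for all coreclust-specific failures."""


class ParameterError(CoreclustError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class AlignmentFormatError(CoreclustError, ValueError):
    """The alignment file could not be parsed in the requested dialect."""


class EmptyCoreError(CoreclustError, ValueError):
    """No alignment column is ungapped in every selected sequence."""


class StructureError(CoreclustError, ValueError):
    """A PDB file or model collection violates the loader's contract."""


class GeometryError(CoreclustError, ValueError):
    """Superposition inputs are mismatched or degenerate."""


class ClusteringError(CoreclustError, ValueError):
    """Clustering could not run or the cutoff search did not terminate."""


class SelectionError(CoreclustError, ValueError):
    """No model of the target sequence was available for selection."""


class EvaluationError(CoreclustError, ValueError):
    """Model evaluation inputs are inconsistent."""
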