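"""Typed exceptions shared across the toolkit."""


class BoxccError(Exception):
    """Base class for all toolkit errors."""


class FormatError(BoxccError):
    """A coordinate or map file could not be parsed in the requested dialect."""


class MissingCellError(FormatError):
    """Coordinate file carries no unit cell; the caller may supply one."""


class UnknownElementError(BoxccError):
    """Element has no entry in the active scattering table."""


class DegenerateBoxError(BoxccError):
    """A voxel box has zero variance (empty or flat density region).

    Raised instead of silently returning 0 so that empty solvent regions
    cannot corrupt correlation scores or training labels.
    """


class CellMismatchError(BoxccError):
    """Structure and map disagree on the unit cell beyond tolerance."""


class GridTooCoarseError(BoxccError):
    """FFT grid does not satisfy the Nyquist condition for d_min."""


class NoLigandError(BoxccError):
    """Bound/unbound structure pair contains no ligand difference."""


class ClashError(BoxccError):
    """Synthetic geometry generation failed to resolve atomic clashes."""
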