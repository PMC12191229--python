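"""Exception hierarchy shared across the pipeline."""


class ImcPhenoError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ImcPhenoError, ValueError):
    """Malformed input file (panel CSV, TIFF stack, cell-table TSV)."""


class ConfigurationError(ImcPhenoError, ValueError):
    """Invalid parameter combination or pipeline configuration."""


class DegenerateInputError(ImcPhenoError, ValueError):
    """Input is valid but carries no usable signal (e.g. a constant image)."""


class PlacementError(ImcPhenoError, RuntimeError):
    """Cell placement failed; carries the number of cells actually placed."""

    def __init__(self, requested: int, placed: int):
        self.requested = requested
        self.placed = placed
        super().__init__(
            f"could only place {placed} of {requested} requested cells "
            f"without overlap; enlarge the image or reduce n_cells/cell_radius"
        )
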