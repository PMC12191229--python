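"""Marker panel: marker names, metal tags and compartment assignments.

An IMC antibody panel assigns every marker to the cellular compartment in
which its signal is expected: ``dna`` for the iridium intercalator channels,
``nuclear`` for markers read out over the nucleus, ``membrane`` for surface
markers, and ``excluded`` for channels ignored by the analysis.  The
compartment drives which channels enter the nuclear/membrane/combined
composite images used for segmentation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError

COMPARTMENTS = ("nuclear", "membrane", "dna", "excluded")


@dataclass(frozen=True)
class PanelEntry:
    marker: str
    metal: str
    compartment: str

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise FormatError(
                f"unknown compartment {self.compartment!r} for marker "
                f"{self.marker!r}; expected one of {COMPARTMENTS}"
            )


class MarkerPanel:
    """Ordered collection of panel entries with unique marker names."""

    def __init__(self, entries: Iterable[PanelEntry]):
        entries = list(entries)
        seen = set()
        for e in entries:
            if e.marker in seen:
                raise FormatError(f"duplicate marker {e.marker!r} in panel")
            seen.add(e.marker)
        if not any(e.compartment == "dna" for e in entries):
            raise FormatError("panel must contain at least one dna channel")
        self.entries: Sequence[PanelEntry] = tuple(entries)
        self._by_name = {e.marker: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, marker: str) -> bool:
        return marker in self._by_name

    def __iter__(self):
        return iter(self.entries)

    @property
    def markers(self) -> list[str]:
        return [e.marker for e in self.entries]

    def compartment(self, marker: str) -> str:
        return self._by_name[marker].compartment

    def markers_for(self, which: str) -> list[str]:
        """Markers contributing to a composite of kind *which*.

        ``nuclear`` includes the dna channels (the nucleus composite is
        built from everything read out over the nucleus), ``membrane`` is
        the surface markers only, and ``combined`` is their union.
        """
        if which == "nuclear":
            allowed = {"nuclear", "dna"}
        elif which == "membrane":
            allowed = {"membrane"}
        elif which == "combined":
            allowed = {"nuclear", "membrane", "dna"}
        elif which == "dna":
            allowed = {"dna"}
        else:
            raise ValueError(f"unknown compartment selector {which!r}")
        return [e.marker for e in self.entries if e.compartment in allowed]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_csv(cls, path) -> "MarkerPanel":
        df = pd.read_csv(path, dtype=str)
        required = {"marker", "metal", "compartment"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"panel CSV missing columns: {sorted(missing)}")
        entries = []
        for i, row in df.iterrows():
            comp = str(row["compartment"]).strip()
            if comp not in COMPARTMENTS:
                raise FormatError(
                    f"row {i}: unknown compartment {comp!r} "
                    f"(marker {row['marker']!r})"
                )
            entries.append(PanelEntry(str(row["marker"]), str(row["metal"]), comp))
        return cls(entries)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "marker": [e.marker for e in self.entries],
                "metal": [e.metal for e in self.entries],
                "compartment": [e.compartment for e in self.entries],
            }
        )
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)


def read_panel(path) -> MarkerPanel:
    return MarkerPanel.from_csv(path)


def write_panel(panel: MarkerPanel, path) -> None:
    panel.to_csv(path)


#: 23-channel mouse tumor-immune-microenvironment panel: two iridium DNA
#: channels, nucleus-scored markers (proliferation, granulocyte and B-cell
#: markers scored over the nucleus in this workflow) and surface markers.
_DEFAULT_ROWS = [
    ("DNA1", "191Ir", "dna"),
    ("DNA2", "193Ir", "dna"),
    ("Ki67", "168Er", "nuclear"),
    ("Ly6G", "141Pr", "nuclear"),
    ("B220", "144Nd", "nuclear"),
    ("F4/80", "146Nd", "nuclear"),
    ("S100A8", "147Sm", "nuclear"),
    ("S100A9", "148Nd", "nuclear"),
    ("CD4", "145Nd", "membrane"),
    ("CD8a", "153Eu", "membrane"),
    ("CD11b", "143Nd", "membrane"),
    ("CD11c", "209Bi", "membrane"),
    ("CD44", "166Er", "membrane"),
    ("CD62L", "149Sm", "membrane"),
    ("CD68", "159Tb", "membrane"),
    ("Pan-CK", "174Yb", "membrane"),
    ("Vimentin", "154Sm", "membrane"),
    ("PD-L1", "150Nd", "membrane"),
    ("PD-1", "155Gd", "membrane"),
    ("FoxP3", "165Ho", "nuclear"),
    ("CD127", "176Yb", "membrane"),
    ("Ly6C", "162Dy", "membrane"),
    ("CD163", "164Dy", "membrane"),
]


def default_panel() -> MarkerPanel:
    """The built-in 23-marker panel used by the synthetic scenes."""
    return MarkerPanel(PanelEntry(*row) for row in _DEFAULT_ROWS)
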