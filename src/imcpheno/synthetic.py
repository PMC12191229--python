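"""Synthetic multiplexed scenes, cell tables and lesion series with ground truth.

The generator emulates the data this pipeline is designed for: a ~23-marker
IMC panel acquired at 1 um/pixel over tissue containing spatially mixed
populations — tumor cells (Vimentin+/CD44+/Pan-CK+), macrophages (F4/80+),
neutrophils (S100A8/A9+), T cells (CD4/CD8a) and B cells (B220) — with
right-skewed (lognormal) marker intensities over a noisy additive background.
Cells are discs: a nuclear core of 0.6x the cell radius carrying the DNA and
nucleus-scored markers, and a membrane annulus carrying the surface markers.
Every output comes with its ground truth, so each downstream stage can be
scored against a known answer.

Serial-section lesion series emulate histological scoring input: per sample a
fixed number of sections (default 10, cut every 150 um), each carrying a
Poisson number of metastatic lesions with lognormal diameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PlacementError
from .images import MultichannelImage
from .panel import MarkerPanel, default_panel


@dataclass(frozen=True)
class Phenotype:
    """A cell population: name, mean intensity per expressed marker, proportion."""

    name: str
    means: dict[str, float]
    proportion: float


#: mean intensities per expressed marker for the five default populations;
#: unlisted markers are not expressed (background only)
DEFAULT_PHENOTYPES = (
    Phenotype("tumor", {"Vimentin": 8.0, "CD44": 8.0, "Pan-CK": 6.0, "Ki67": 3.0}, 0.40),
    Phenotype("macrophage", {"F4/80": 8.0, "CD68": 6.0, "CD11b": 5.0}, 0.20),
    Phenotype("neutrophil", {"S100A8": 8.0, "S100A9": 8.0, "Ly6G": 6.0, "CD11b": 3.0}, 0.15),
    Phenotype("t_cell", {"CD4": 6.0, "CD8a": 6.0, "CD62L": 4.0, "CD127": 3.0}, 0.15),
    Phenotype("b_cell", {"B220": 8.0, "CD62L": 3.0}, 0.10),
)

#: DNA intercalator signal painted into every nucleus regardless of phenotype
DNA_MEAN = 10.0


@dataclass
class SceneSpec:
    """Parameters of one synthetic multichannel scene."""

    image_height_px: int = 256
    image_width_px: int = 256
    pixel_size_um: float = 1.0  # matches 1 um/pixel laser ablation
    phenotypes: tuple[Phenotype, ...] = DEFAULT_PHENOTYPES
    n_cells: int = 200
    cell_radius_um: float = 5.0
    intensity_noise_sd: float = 0.3  # sigma of the lognormal multiplicative noise
    background_level: float = 1.0
    background_noise_sd: float = 0.3
    min_center_distance_factor: float = 2.0  # dart-throwing exclusion, x cell_radius
    seed: int = 0

    def __post_init__(self):
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be nonnegative")
        if self.cell_radius_um <= 0:
            raise ValueError("cell_radius_um must be positive")
        if self.intensity_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise and background must be nonnegative")
        props = [p.proportion for p in self.phenotypes]
        if self.phenotypes and abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"phenotype proportions sum to {sum(props)}, not 1")
        for p in self.phenotypes:
            if any(v < 0 for v in p.means.values()):
                raise ValueError(f"phenotype {p.name!r} has a negative marker mean")

    def validate_against_panel(self, panel: MarkerPanel) -> None:
        for p in self.phenotypes:
            unknown = [m for m in p.means if m not in panel]
            if unknown:
                raise ValueError(
                    f"phenotype {p.name!r} uses markers not in panel: {unknown}"
                )


@dataclass
class GroundTruth:
    """True cell geometry and identity for a generated scene."""

    label_grid: np.ndarray  # integer grid, 0 = background
    phenotype_per_cell: dict[int, str]
    centroids_um: dict[int, tuple[float, float]]  # cell id -> (x, y)

    @property
    def n_cells(self) -> int:
        return len(self.phenotype_per_cell)


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing placement with a hard minimum center distance."""
    r_px = spec.cell_radius_um / spec.pixel_size_um
    min_d2 = (spec.min_center_distance_factor * r_px) ** 2
    lo_r, hi_r = r_px, spec.image_height_px - 1 - r_px
    lo_c, hi_c = r_px, spec.image_width_px - 1 - r_px
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError(spec.n_cells, 0)
    centers: list[tuple[float, float]] = []
    max_retries = 50
    for i in range(spec.n_cells):
        for _ in range(max_retries):
            rr = rng.uniform(lo_r, hi_r)
            cc = rng.uniform(lo_c, hi_c)
            if all((rr - pr) ** 2 + (cc - pc) ** 2 >= min_d2 for pr, pc in centers):
                centers.append((rr, cc))
                break
        else:
            raise PlacementError(spec.n_cells, len(centers))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def make_scene(
    spec: SceneSpec, panel: MarkerPanel | None = None
) -> tuple[MultichannelImage, GroundTruth]:
    """Render one multichannel scene and its ground truth.

    Deterministic given ``spec.seed``: a single RNG stream drives placement,
    phenotype assignment, per-cell intensity draws and background noise.
    """
    panel = panel if panel is not None else default_panel()
    spec.validate_against_panel(panel)
    rng = np.random.default_rng(spec.seed)

    h, w = spec.image_height_px, spec.image_width_px
    centers = _place_centers(spec, rng)
    n = len(centers)

    if spec.phenotypes:
        props = np.array([p.proportion for p in spec.phenotypes])
        pheno_idx = rng.choice(len(spec.phenotypes), size=n, p=props)
    else:
        pheno_idx = np.zeros(n, dtype=int)

    r_px = spec.cell_radius_um / spec.pixel_size_um
    r_nuc = 0.6 * r_px
    rows, cols = np.mgrid[0:h, 0:w]

    label_grid = np.zeros((h, w), dtype=np.int32)
    channels = {m: np.zeros((h, w)) for m in panel.markers}
    phenotype_per_cell: dict[int, str] = {}
    centroids: dict[int, tuple[float, float]] = {}

    nuclear_markers = set(panel.markers_for("nuclear"))  # includes dna
    dna_markers = set(panel.markers_for("dna"))

    for i, (rr, cc) in enumerate(centers):
        cid = i + 1
        pheno = spec.phenotypes[pheno_idx[i]] if spec.phenotypes else None
        phenotype_per_cell[cid] = pheno.name if pheno else "cell"
        centroids[cid] = (cc * spec.pixel_size_um, rr * spec.pixel_size_um)

        r0 = max(int(math.floor(rr - r_px)) - 1, 0)
        r1 = min(int(math.ceil(rr + r_px)) + 2, h)
        c0 = max(int(math.floor(cc - r_px)) - 1, 0)
        c1 = min(int(math.ceil(cc + r_px)) + 2, w)
        d2 = (rows[r0:r1, c0:c1] - rr) ** 2 + (cols[r0:r1, c0:c1] - cc) ** 2
        cell = d2 <= r_px**2
        nucleus = d2 <= r_nuc**2
        annulus = cell & ~nucleus

        label_grid[r0:r1, c0:c1][cell] = cid

        means = dict(pheno.means) if pheno else {}
        for m in dna_markers:
            means.setdefault(m, DNA_MEAN)
        for m, mu in means.items():
            if mu <= 0:
                continue
            level = mu * (
                math.exp(spec.intensity_noise_sd * rng.standard_normal())
                if spec.intensity_noise_sd > 0
                else 1.0
            )
            region = nucleus if m in nuclear_markers else annulus
            channels[m][r0:r1, c0:c1][region] += level

    if spec.background_level > 0:
        for m in panel.markers:
            bg = rng.normal(spec.background_level, spec.background_noise_sd, size=(h, w))
            channels[m] += np.clip(bg, 0.0, None)

    image = MultichannelImage(channels=channels, pixel_size_um=spec.pixel_size_um)
    truth = GroundTruth(label_grid, phenotype_per_cell, centroids)
    return image, truth


def make_cell_table(
    spec: SceneSpec,
    panel: MarkerPanel | None = None,
    n_samples: int = 1,
    condition_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw cell tables directly, bypassing imaging.

    Returns ``(table, truth)``: the cell table (one row per cell, marker
    intensities drawn from the cell's phenotype means with lognormal noise,
    plus DNA signal and the truncated-Gaussian background every marker picks
    up in a real acquisition) and a separate ground-truth frame with the
    hidden phenotype labels.  Sample ids are ``sample_01 ..``;
    ``condition_map`` assigns each a condition label (default: every sample
    ``"control"``).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    panel = panel if panel is not None else default_panel()
    spec.validate_against_panel(panel)
    rng = np.random.default_rng(spec.seed)

    sample_ids = [f"sample_{i + 1:02d}" for i in range(n_samples)]
    if condition_map is None:
        condition_map = {s: "control" for s in sample_ids}
    missing = [s for s in sample_ids if s not in condition_map]
    if missing:
        raise ValueError(f"condition_map missing samples: {missing}")

    props = np.array([p.proportion for p in spec.phenotypes])
    markers = panel.markers
    dna_markers = set(panel.markers_for("dna"))
    rows = []
    truth_rows = []
    w_um = spec.image_width_px * spec.pixel_size_um
    h_um = spec.image_height_px * spec.pixel_size_um
    for sid in sample_ids:
        idx = rng.choice(len(spec.phenotypes), size=spec.n_cells, p=props)
        xs = rng.uniform(0, w_um, size=spec.n_cells)
        ys = rng.uniform(0, h_um, size=spec.n_cells)
        for j in range(spec.n_cells):
            pheno = spec.phenotypes[idx[j]]
            vals = {}
            for m in markers:
                mu = pheno.means.get(m, DNA_MEAN if m in dna_markers else 0.0)
                v = mu
                if mu > 0 and spec.intensity_noise_sd > 0:
                    v = mu * math.exp(
                        spec.intensity_noise_sd * rng.standard_normal()
                    )
                if spec.background_level > 0:
                    bg = spec.background_level
                    if spec.background_noise_sd > 0:
                        bg = max(
                            rng.normal(bg, spec.background_noise_sd), 0.0
                        )
                    v += bg
                vals[m] = v
            rows.append(
                {
                    "cell_id": j + 1,
                    "x_um": xs[j],
                    "y_um": ys[j],
                    "sample_id": sid,
                    "condition": condition_map[sid],
                    **vals,
                }
            )
            truth_rows.append(
                {"sample_id": sid, "cell_id": j + 1, "phenotype": pheno.name}
            )
    table = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "sample_id", "condition"] + markers)
    truth = pd.DataFrame(truth_rows, columns=["sample_id", "cell_id", "phenotype"])
    return table, truth


@dataclass
class LesionSeriesSpec:
    """Parameters of a serial-section lesion table."""

    n_samples: int = 5
    sections_per_sample: int = 10  # 10 sections collected per sample
    section_spacing_um: float = 150.0  # sections cut every 150 um
    lesions_per_section_rate: float = 2.0
    diameter_log_mean: float = math.log(0.8)  # lognormal diameters, mm
    diameter_log_sd: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.sections_per_sample < 1:
            raise ValueError("n_samples and sections_per_sample must be >= 1")
        if self.section_spacing_um <= 0:
            raise ValueError("section_spacing_um must be positive")
        if self.lesions_per_section_rate < 0:
            raise ValueError("lesion rate must be nonnegative")
        if self.diameter_log_sd < 0:
            raise ValueError("diameter_log_sd must be nonnegative")


def make_lesion_series(spec: LesionSeriesSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-section lesion diameters and the true per-sample scores.

    Returns ``(lesions, truth)``: a long table with one row per lesion
    (sample_id, section_index, diameter_mm) — samples or sections with no
    lesions simply contribute no rows, but every section index 1..S exists
    for every sample in the truth bookkeeping — and a per-sample frame with
    the true total score computed from the size-bin map.
    """
    from .scoring import score_lesion  # local import: scoring is downstream

    rng = np.random.default_rng(spec.seed)
    rows = []
    truth_rows = []
    for i in range(spec.n_samples):
        sid = f"sample_{i + 1:02d}"
        total = 0
        count = 0
        for s in range(1, spec.sections_per_sample + 1):
            k = rng.poisson(spec.lesions_per_section_rate)
            if k > 0:
                diams = np.exp(
                    rng.normal(spec.diameter_log_mean, spec.diameter_log_sd, size=k)
                )
                for d in diams:
                    rows.append(
                        {"sample_id": sid, "section_index": s, "diameter_mm": float(d)}
                    )
                    total += score_lesion(float(d))
                    count += 1
        truth_rows.append(
            {
                "sample_id": sid,
                "n_sections": spec.sections_per_sample,
                "n_lesions": count,
                "true_total_score": total,
            }
        )
    lesions = pd.DataFrame(rows, columns=["sample_id", "section_index", "diameter_mm"])
    truth = pd.DataFrame(truth_rows)
    return lesions, truth
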