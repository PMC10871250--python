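"""Synthetic ground-truth data generators.

Three generators back the downstream analysis stages:

* :func:`generate_field` / :func:`generate_timecourse` — fluorescence
  microscopy fields of adherent cells (nuclear + reporter channel) with
  condensing cytoplasmic puncta, plus exact geometric truth tables.
* :func:`generate_counts` — paired RNA-seq/Ribo-seq negative-binomial count
  matrices with library-size factors and planted regulatory gene classes.
* :func:`generate_melt_curve` — sigmoidal thermal-denaturation fluorescence
  curves with a known melting temperature.

All generators take an explicit seed, use one private RNG stream per call,
and are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = [
    "FieldSpec",
    "SyntheticField",
    "CountDesign",
    "MeltCurve",
    "GENE_CLASSES",
    "generate_field",
    "generate_timecourse",
    "generate_counts",
    "generate_melt_curve",
]


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# microscopy fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldSpec:
    """Geometry and photometry of one synthetic imaging field.

    Lengths are in pixels, intensities in arbitrary photon-count units and
    times in minutes. Defaults emulate a 20x widefield view of adherent
    human cells (U-2OS-like): ~20 cells per field, nuclei ~8 px radius,
    cell bodies ~20 px, and bright sub-micron puncta of ~2.5 px radius that
    condense between ``condensation_onset`` and ``condensation_offset``.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 20
    nucleus_radius: tuple[float, float] = (8.0, 1.0)      # (mean, sd)
    cell_radius: tuple[float, float] = (20.0, 2.0)        # (mean, sd)
    foci_per_cell_mean: float = 2.5                       # Poisson rate
    focus_radius: tuple[float, float] = (2.5, 0.4)        # (mean, sd) semi-major
    focus_axis_ratio: float = 1.0                         # b/a in (0, 1]
    background_intensity: float = 100.0
    cytoplasm_intensity: float = 500.0
    nucleus_reporter_intensity: float = 350.0             # nuclei darker than cytoplasm
    nucleus_nuclear_intensity: float = 2000.0
    focus_intensity: float = 2000.0
    noise_sd: float = 50.0
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 601, 30))
    condensation_onset: float = 30.0
    condensation_offset: float = 150.0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if min(self.nucleus_radius[0], self.cell_radius[0], self.focus_radius[0]) <= 0:
            raise ValueError("radii must be positive")
        if not (0.0 < self.focus_axis_ratio <= 1.0):
            raise ValueError("focus_axis_ratio must lie in (0, 1]")
        for name in ("background_intensity", "cytoplasm_intensity",
                     "nucleus_reporter_intensity", "nucleus_nuclear_intensity",
                     "focus_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def replace(self, **kw) -> "FieldSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticField:
    """One rendered field plus its exact ground truth.

    ``truth_cells`` columns: cell_id, row, col, nucleus_radius, cell_radius,
    n_foci, total_foci_area, reporter_mean.
    ``truth_foci`` columns: focus_id, cell_id, row, col, semi_major,
    semi_minor, theta, area, eccentricity.
    """

    nuclear_channel: np.ndarray
    reporter_channel: np.ndarray
    truth_cells: pd.DataFrame
    truth_foci: pd.DataFrame
    timepoint: float = 0.0

    # noiseless focus-only layer, pre-blur; used by rendering/truth checks
    focus_mask: np.ndarray | None = None


_CELL_COLUMNS = ["cell_id", "row", "col", "nucleus_radius", "cell_radius",
                 "n_foci", "total_foci_area", "reporter_mean"]
_FOCI_COLUMNS = ["focus_id", "cell_id", "row", "col", "semi_major",
                 "semi_minor", "theta", "area", "eccentricity"]


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, a, b, theta):
    """Filled rotated ellipse with semi-axes a >= b; pixel-center rasterization."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_cells(spec: FieldSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping cell positions and radii."""
    h, w = spec.image_size
    cells = []
    max_tries = 200 * max(spec.n_cells, 1)
    tries = 0
    while len(cells) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.n_cells} non-overlapping cells of "
                f"radius ~{spec.cell_radius[0]} in a {h}x{w} field "
                f"after {max_tries} attempts"
            )
        tries += 1
        r_cell = max(rng.normal(*spec.cell_radius), spec.nucleus_radius[0] + 3)
        r_nuc = float(np.clip(rng.normal(*spec.nucleus_radius), 2.0, r_cell - 2.0))
        row = rng.uniform(r_cell + 1, h - r_cell - 1)
        col = rng.uniform(r_cell + 1, w - r_cell - 1)
        if all((row - c[0]) ** 2 + (col - c[1]) ** 2 > (r_cell + c[2] + 2) ** 2
               for c in cells):
            cells.append((row, col, r_cell, r_nuc))
    return cells


def _sample_foci(spec, rng, cells, n_foci_per_cell):
    """Place non-overlapping elliptical foci inside each cell's cytoplasm."""
    foci = []
    fid = 0
    for cid, ((row, col, r_cell, r_nuc), n_foci) in enumerate(
            zip(cells, n_foci_per_cell), start=1):
        placed = []
        for _ in range(n_foci):
            a = max(rng.normal(*spec.focus_radius), 1.0)
            b = a * spec.focus_axis_ratio
            theta = rng.uniform(0, np.pi)
            for _try in range(200):
                # annulus between nucleus and cell edge, with margins
                lo = r_nuc + a + 1.0
                hi = r_cell - a - 1.0
                if hi <= lo:  # cell too small: drop this focus
                    break
                rad = rng.uniform(lo, hi)
                ang = rng.uniform(0, 2 * np.pi)
                fr = row + rad * np.sin(ang)
                fc = col + rad * np.cos(ang)
                # keep foci apart so detection truth is unambiguous
                if all((fr - p[0]) ** 2 + (fc - p[1]) ** 2 > (a + p[2] + 2) ** 2
                       for p in placed):
                    placed.append((fr, fc, a))
                    fid += 1
                    foci.append((fid, cid, fr, fc, a, b, theta))
                    break
    return foci


def generate_field(spec: FieldSpec, seed: int, *, n_foci_override=None,
                   timepoint: float = 0.0,
                   noise_seed: int | None = None) -> SyntheticField:
    """Render one two-channel field and its ground-truth tables.

    Cells are disks of uniform cytoplasmic intensity with a darker
    (reporter channel) / bright (nuclear channel) nuclear disk; puncta are
    hard-edged filled ellipses. The noiseless composite is blurred by a
    0.5 px Gaussian to emulate optics, then i.i.d. Gaussian read noise is
    added. Truth areas are exact rasterized pixel counts of the pre-blur
    ellipse masks.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.image_size

    cells = _place_cells(spec, rng)
    if n_foci_override is not None:
        n_foci_per_cell = [int(n_foci_override)] * len(cells)
    else:
        n_foci_per_cell = rng.poisson(spec.foci_per_cell_mean, size=len(cells))
    foci = _sample_foci(spec, rng, cells, n_foci_per_cell)

    nuclear = np.full((h, w), spec.background_intensity, dtype=float)
    reporter = np.full((h, w), spec.background_intensity, dtype=float)
    focus_mask = np.zeros((h, w), dtype=bool)

    cell_rows = []
    for cid, (row, col, r_cell, r_nuc) in enumerate(cells, start=1):
        body = _disk_mask((h, w), (row, col), r_cell)
        nuc = _disk_mask((h, w), (row, col), r_nuc)
        reporter[body] = spec.cytoplasm_intensity
        reporter[nuc] = spec.nucleus_reporter_intensity
        nuclear[nuc] = spec.nucleus_nuclear_intensity
        cell_rows.append([cid, row, col, r_nuc, r_cell, 0, 0.0,
                          spec.cytoplasm_intensity])

    foci_rows = []
    for fid, cid, fr, fc, a, b, theta in foci:
        m = _ellipse_mask((h, w), (fr, fc), a, b, theta)
        area = int(m.sum())
        if area == 0:
            continue
        reporter[m] = spec.focus_intensity
        focus_mask |= m
        ecc = float(np.sqrt(1.0 - (b / a) ** 2))
        foci_rows.append([fid, cid, fr, fc, a, b, theta, area, ecc])
        cell_rows[cid - 1][5] += 1
        cell_rows[cid - 1][6] += area

    # optics blur on the noiseless composite, then read noise
    reporter = ndi.gaussian_filter(reporter, sigma=0.5)
    nuclear = ndi.gaussian_filter(nuclear, sigma=0.5)
    if spec.noise_sd > 0:
        noise_rng = rng if noise_seed is None else np.random.default_rng(noise_seed)
        nuclear = nuclear + noise_rng.normal(0.0, spec.noise_sd, size=(h, w))
        reporter = reporter + noise_rng.normal(0.0, spec.noise_sd, size=(h, w))
    nuclear = np.clip(nuclear, 0, None)
    reporter = np.clip(reporter, 0, None)

    truth_cells = pd.DataFrame(cell_rows, columns=_CELL_COLUMNS)
    truth_foci = pd.DataFrame(foci_rows, columns=_FOCI_COLUMNS)
    return SyntheticField(nuclear, reporter, truth_cells, truth_foci,
                          timepoint=timepoint, focus_mask=focus_mask)


def generate_timecourse(spec: FieldSpec, seed: int) -> list[SyntheticField]:
    """Render the same field at each ``spec.timepoints``.

    Cell positions persist across timepoints (same geometry seed); puncta
    are present only for onset <= t < offset, emulating transient granule
    condensation and disassembly under acute stress.
    """
    spec.validate()
    if not spec.timepoints:
        raise ValueError("spec.timepoints must be nonempty")
    fields = []
    for i, t in enumerate(spec.timepoints):
        condensed = spec.condensation_onset <= t < spec.condensation_offset
        f = generate_field(spec, seed, timepoint=float(t),
                           n_foci_override=None if condensed else 0,
                           noise_seed=(seed + 1) * 1000 + i)
        fields.append(f)
    return fields


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

GENE_CLASSES = (
    "NULL",
    "TE_UP", "TE_DOWN",
    "BUFFERING_UP", "BUFFERING_DOWN",
    "RNA_ABUNDANCE_UP", "RNA_ABUNDANCE_DOWN",
    "RIBO_OCP_UP", "RIBO_OCP_DOWN",
)


def _class_lfcs(label: str, effect: float) -> tuple[float, float]:
    """(rna_lfc, ribo_lfc) in the treated condition for a planted class.

    TE changes occupancy only; BUFFERING changes mRNA only; RNA_ABUNDANCE
    changes both concordantly; RIBO_OCP shifts occupancy by the full effect
    with a half-effect mRNA change (occupancy outrunning abundance).
    """
    e = abs(effect)
    sign = -1.0 if label.endswith("_DOWN") else 1.0
    if label == "NULL":
        return 0.0, 0.0
    if label.startswith("TE_"):
        return 0.0, sign * e
    if label.startswith("BUFFERING_"):
        return sign * e, 0.0
    if label.startswith("RNA_ABUNDANCE_"):
        return sign * e, sign * e
    if label.startswith("RIBO_OCP_"):
        return sign * e / 2.0, sign * e
    raise ValueError(f"unknown gene class {label!r}")


@dataclass
class CountDesign:
    """Design of a paired RNA/Ribo negative-binomial count simulation.

    Counts for gene g in sample s are NB with mean
    ``size_factor_s * baseline_mean_g * 2**lfc(g, s)`` and dispersion
    ``alpha_g`` (variance = mu + alpha * mu**2, the DESeq2 convention).
    ``class_fractions`` allocates genes to planted regulatory classes; all
    non-allocated genes are NULL.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    conditions: tuple[str, str] = ("control", "treated")
    genotype: str = "WT"
    baseline_mean: tuple[float, float] = (4.0, 1.0)   # lognormal (mean, sd) of ln q_g
    dispersion: float = 0.05                          # alpha, shared default
    effect_lfc: float = 2.0
    class_fractions: dict = field(default_factory=lambda: {
        "TE_UP": 0.025, "TE_DOWN": 0.025,
        "BUFFERING_UP": 0.025, "BUFFERING_DOWN": 0.025,
        "RNA_ABUNDANCE_UP": 0.025, "RNA_ABUNDANCE_DOWN": 0.025,
        "RIBO_OCP_UP": 0.0, "RIBO_OCP_DOWN": 0.0,
    })
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    size_factors: np.ndarray | None = None            # optional explicit per-sample
    baseline_means: np.ndarray | None = None          # optional explicit per-gene
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates < 2:
            raise ValueError("at least 2 replicates per (assay, condition)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.size_factors is not None and np.any(np.asarray(self.size_factors) <= 0):
            raise ValueError("size factors must be positive")
        bad = set(self.class_fractions) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        if sum(self.class_fractions.values()) > 1.0 + 1e-12:
            raise ValueError("class fractions sum above 1")

    @property
    def samples(self) -> pd.DataFrame:
        rows = []
        for assay in ("RNA", "RIBO"):
            for cond in self.conditions:
                for rep in range(1, self.n_replicates + 1):
                    rows.append({
                        "sample": f"{assay}_{cond}_r{rep}",
                        "assay": assay,
                        "genotype": self.genotype,
                        "condition": cond,
                        "replicate": rep,
                    })
        return pd.DataFrame(rows).set_index("sample")


def generate_counts(design: CountDesign):
    """Simulate paired RNA/Ribo NB counts with planted gene classes.

    Returns ``(counts, metadata, truth)`` where ``counts`` is a
    genes x samples integer DataFrame, ``metadata`` the per-sample design
    table, and ``truth`` records each gene's class, effect and true
    per-assay LFC plus the noiseless mean matrix (``truth.attrs["mean"]``).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    meta = design.samples
    n_samp = len(meta)

    if design.baseline_means is not None:
        q = np.asarray(design.baseline_means, dtype=float)
        if len(q) != design.n_genes or np.any(q <= 0):
            raise ValueError("baseline_means must be positive, length n_genes")
    else:
        q = rng.lognormal(design.baseline_mean[0], design.baseline_mean[1],
                          size=design.n_genes)

    if design.size_factors is not None:
        sf = np.asarray(design.size_factors, dtype=float)
        if len(sf) != n_samp:
            raise ValueError("size_factors must have one entry per sample")
    else:
        sf = rng.uniform(*design.size_factor_range, size=n_samp)

    # planted classes
    labels = np.array(["NULL"] * design.n_genes, dtype=object)
    order = rng.permutation(design.n_genes)
    pos = 0
    for cls, frac in design.class_fractions.items():
        k = int(round(frac * design.n_genes))
        labels[order[pos:pos + k]] = cls
        pos += k

    rna_lfc = np.zeros(design.n_genes)
    ribo_lfc = np.zeros(design.n_genes)
    for i, lab in enumerate(labels):
        rna_lfc[i], ribo_lfc[i] = _class_lfcs(lab, design.effect_lfc)

    treated = (meta["condition"] == design.conditions[1]).to_numpy()
    is_ribo = (meta["assay"] == "RIBO").to_numpy()
    # per-gene x per-sample log2 contribution
    lfc_gs = (np.outer(rna_lfc, treated & ~is_ribo)
              + np.outer(ribo_lfc, treated & is_ribo))
    mu = sf[None, :] * q[:, None] * np.exp2(lfc_gs)

    alpha = design.dispersion
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    genes = [f"gene{i:05d}" for i in range(design.n_genes)]
    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = pd.DataFrame({
        "gene": genes,
        "label": labels,
        "effect_lfc": np.where(labels == "NULL", 0.0, design.effect_lfc),
        "rna_lfc": rna_lfc,
        "ribo_lfc": ribo_lfc,
        "baseline_mean": q,
    }).set_index("gene")
    truth.attrs["mean"] = pd.DataFrame(mu, index=genes, columns=meta.index)
    truth.attrs["size_factors"] = pd.Series(sf, index=meta.index)
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

@dataclass
class MeltCurve:
    """A thermal-denaturation fluorescence curve on a uniform °C grid."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    true_tm: float | None = None

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        self.temperature = t
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence must share shape")


def generate_melt_curve(true_tm: float, steepness: float = 1.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        amplitude: float = 100.0,
                        baseline: float = 10.0) -> MeltCurve:
    """Logistic melt curve on the instrument grid (25→95 °C, 0.2 °C steps).

    Fluorescence rises sigmoidally with inflection at ``true_tm``;
    ``steepness`` is the logistic rate per °C; Gaussian noise of sd
    ``noise_sd`` (same units as ``amplitude``) is added.
    """
    if not (25.0 <= true_tm <= 95.0):
        raise ValueError("true_tm must lie in [25, 95] °C")
    if steepness <= 0:
        raise ValueError("steepness must be positive")
    rng = np.random.default_rng(seed)
    temperature = 25.0 + 0.2 * np.arange(int(round((95.0 - 25.0) / 0.2)) + 1)
    fl = baseline + amplitude / (1.0 + np.exp(-steepness * (temperature - true_tm)))
    if noise_sd > 0:
        fl = fl + rng.normal(0.0, noise_sd, size=fl.shape)
    return MeltCurve(temperature, fl, true_tm=true_tm)
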