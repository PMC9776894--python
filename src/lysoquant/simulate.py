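"""Ground-truthed simulators for every analysis stage.

Three generators produce the inputs the pipelines consume, each with a full
ground-truth record so recovery can be asserted rather than eyeballed:

* :func:`generate_cell_image` — fluorescence fields with disk nuclei and
  cytoplasms and Gaussian organelle puncta. Juxtanuclear clustering is a
  mixture: a fraction ``kappa`` of each cell's puncta is placed in a band
  abutting the nucleus, the rest uniformly in the cytoplasm, so ``kappa=0``
  is the spatially uniform null and ``kappa=1`` full perinuclear clustering.
* :func:`generate_lipidome` — a multi-class lipidome (defaults follow a
  typical cultured-cell composition across the monitored classes) with
  planted log2 fold changes, per-species batch effects, log-normal
  measurement noise and per-class internal standards.
* :func:`generate_plate` — long-format plate tables (LDH cytotoxicity,
  luciferase flux, PI counts) from exact signal models plus additive noise.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import LabelMask, MultiChannelImage
from .lipidomics import CLASS_CATEGORY, LipidTable, lipid_category

__all__ = [
    "ImageSimParams",
    "ImageGroundTruth",
    "generate_cell_image",
    "LipidSimParams",
    "LipidSimTruth",
    "generate_lipidome",
    "PlateSimParams",
    "generate_plate",
    "DEFAULT_CLASS_COMPOSITION",
    "DEFAULT_PLANTED_EFFECTS",
]


# --------------------------------------------------------------------- images
@dataclass
class ImageSimParams:
    """Scene parameters for the fluorescence-field simulator.

    ``puncta_channels`` maps organelle channel names to peak spot amplitudes;
    ``punctum_scale_choices``, when given, draws a per-punctum scale factor
    applied to the *first* puncta channel only (used to plant known
    two-channel ratios). Amplitudes are peak heights before PSF blur.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.33
    n_cells: int = 8
    nucleus_radius: tuple[float, float] = (14.0, 20.0)
    cytoplasm_radius: tuple[float, float] = (28.0, 38.0)
    puncta_mean: float = 4.0
    puncta_count: int | None = None
    puncta_channels: dict[str, float] = field(default_factory=lambda: {"LAMP2": 80.0})
    punctum_scale_choices: tuple[float, ...] | None = None
    puncta_sigma_px: float = 1.5
    kappa: float = 0.0
    band_width_px: float = 6.0
    min_separation_px: float = 8.0
    nuclear_amplitude: float = 100.0
    cytoplasm_amplitude: float = 60.0
    background: float | dict[str, float] = 2.0
    noise_sd: float | dict[str, float] = 0.0
    psf_sigma_px: float = 1.0
    margin_px: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        for name, (lo, hi) in (
            ("nucleus_radius", self.nucleus_radius),
            ("cytoplasm_radius", self.cytoplasm_radius),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 < min <= max")
        if self.cytoplasm_radius[0] <= self.nucleus_radius[1]:
            raise ValueError("cytoplasm radii must exceed nucleus radii")
        if self.puncta_sigma_px <= 0:
            raise ValueError("puncta_sigma_px must be positive")
        if self.puncta_mean < 0 or (self.puncta_count is not None and self.puncta_count < 0):
            raise ValueError("puncta counts must be non-negative")
        for v in self._per_channel(self.noise_sd).values():
            if v < 0:
                raise ValueError("noise SD must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    def _per_channel(self, value) -> dict[str, float]:
        names = ["nuclei", "cytoplasm", *self.puncta_channels]
        if isinstance(value, dict):
            return {n: float(value.get(n, 0.0)) for n in names}
        return {n: float(value) for n in names}


@dataclass
class ImageGroundTruth:
    """True scene content: masks, puncta and per-cell counts."""

    nuclei: LabelMask
    cells: LabelMask
    puncta: pd.DataFrame  # cell, row, col, sigma, clustered, amp_<channel>...
    counts: pd.Series  # per-cell true punctum count (zeros included)

    def validate(self) -> None:
        """Self-consistency: counts match the list and every punctum sits
        inside its owning cell's mask."""
        recount = (
            self.puncta["cell"].value_counts().reindex(self.counts.index).fillna(0).astype(int)
        )
        if not recount.equals(self.counts.astype(int)):
            raise AssertionError("per-cell counts inconsistent with punctum list")
        for _, p in self.puncta.iterrows():
            r, c = int(round(p["row"])), int(round(p["col"]))
            if self.cells.labels[r, c] != int(p["cell"]):
                raise AssertionError("punctum centroid outside its owning cell")


def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _add_gaussian(img: np.ndarray, center, sigma: float, amplitude: float) -> None:
    half = int(np.ceil(5 * sigma))
    r0, c0 = center
    rlo, rhi = max(int(r0) - half, 0), min(int(r0) + half + 1, img.shape[0])
    clo, chi = max(int(c0) - half, 0), min(int(c0) + half + 1, img.shape[1])
    rr, cc = np.ogrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def generate_cell_image(
    params: ImageSimParams,
) -> tuple[MultiChannelImage, ImageGroundTruth]:
    """Render a multi-channel field of cells with organelle puncta.

    Cells are non-overlapping disk pairs (nucleus inside cytoplasm) kept
    clear of the image border; puncta are isotropic Gaussian spots placed
    with a minimum pairwise separation, juxtanuclear with probability
    ``kappa``. Rendering is spots/disks -> PSF blur -> background + Gaussian
    noise (clipped at zero). Raises if the field is too crowded to place all
    cells or puncta within bounded retries.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.shape
    margin = params.margin_px
    if margin is None:
        margin = params.cytoplasm_radius[1] + 2.0

    centers: list[tuple[float, float]] = []
    nuc_r: list[float] = []
    cyt_r: list[float] = []
    tries = 0
    max_tries = 400 * params.n_cells
    while len(centers) < params.n_cells:
        tries += 1
        if tries > max_tries:
            density = params.n_cells * np.pi * margin**2 / (H * W)
            raise RuntimeError(
                f"failed to place {params.n_cells} cells in a {H}x{W} field "
                f"after {max_tries} tries (footprint density {density:.2f}); "
                "reduce n_cells or enlarge the field"
            )
        r = rng.uniform(margin, H - margin)
        c = rng.uniform(margin, W - margin)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= (2 * margin) ** 2 for r2, c2 in centers):
            centers.append((r, c))
            nuc_r.append(rng.uniform(*params.nucleus_radius))
            cyt_r.append(rng.uniform(*params.cytoplasm_radius))

    nuclei = np.zeros((H, W), dtype=np.int32)
    cells = np.zeros((H, W), dtype=np.int32)
    for i, (ctr, rn, rc) in enumerate(zip(centers, nuc_r, cyt_r), start=1):
        cells[_disk_mask((H, W), ctr, rc)] = i
        nuclei[_disk_mask((H, W), ctr, rn)] = i

    edge_margin = 3 * params.puncta_sigma_px + params.psf_sigma_px + 1
    chan_names = list(params.puncta_channels)
    records = []
    for i, (ctr, rn, rc) in enumerate(zip(centers, nuc_r, cyt_r), start=1):
        count = (
            params.puncta_count
            if params.puncta_count is not None
            else int(rng.poisson(params.puncta_mean))
        )
        placed: list[tuple[float, float]] = []
        for _ in range(count):
            ok = False
            for _attempt in range(600):
                clustered = bool(rng.random() < params.kappa)
                if clustered:
                    rad = rn + rng.uniform(0.5, params.band_width_px)
                else:
                    r_lo, r_hi = rn + 1.0, rc - edge_margin
                    if r_hi <= r_lo:
                        raise RuntimeError("cytoplasm too thin for uniform puncta")
                    rad = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
                theta = rng.uniform(0, 2 * np.pi)
                pr = ctr[0] + rad * np.sin(theta)
                pc = ctr[1] + rad * np.cos(theta)
                if all(
                    (pr - q[0]) ** 2 + (pc - q[1]) ** 2 >= params.min_separation_px**2
                    for q in placed
                ):
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"failed to place {count} puncta with separation "
                    f">= {params.min_separation_px} px in cell {i}; "
                    "cytoplasm too crowded"
                )
            placed.append((pr, pc))
            scale = (
                float(rng.choice(params.punctum_scale_choices))
                if params.punctum_scale_choices is not None
                else 1.0
            )
            rec = {"cell": i, "row": pr, "col": pc, "sigma": params.puncta_sigma_px,
                   "clustered": clustered}
            for j, ch in enumerate(chan_names):
                amp = params.puncta_channels[ch]
                rec[f"amp_{ch}"] = amp * (scale if j == 0 else 1.0)
            records.append(rec)

    puncta = pd.DataFrame(
        records,
        columns=["cell", "row", "col", "sigma", "clustered"]
        + [f"amp_{ch}" for ch in chan_names],
    )
    counts = (
        puncta["cell"].value_counts().reindex(range(1, params.n_cells + 1)).fillna(0).astype(int)
    )
    counts.index.name = "cell"

    channels: dict[str, np.ndarray] = {
        "nuclei": np.where(nuclei > 0, params.nuclear_amplitude, 0.0),
        "cytoplasm": np.where(cells > 0, params.cytoplasm_amplitude, 0.0),
    }
    for ch in chan_names:
        img = np.zeros((H, W))
        for rec in records:
            _add_gaussian(img, (rec["row"], rec["col"]), rec["sigma"], rec[f"amp_{ch}"])
        channels[ch] = img

    bg = params._per_channel(params.background)
    sd = params._per_channel(params.noise_sd)
    for name in channels:
        arr = channels[name]
        if params.psf_sigma_px > 0:
            arr = gaussian_filter(arr, params.psf_sigma_px)
        arr = arr + bg[name]
        if sd[name] > 0:
            arr = arr + rng.normal(0.0, sd[name], size=arr.shape)
        channels[name] = np.clip(arr, 0.0, None)

    image = MultiChannelImage(channels=channels, pixel_size_um=params.pixel_size_um)
    truth = ImageGroundTruth(
        nuclei=LabelMask(labels=nuclei, kind="nucleus"),
        cells=LabelMask(labels=cells, kind="cell"),
        puncta=puncta,
        counts=counts,
    )
    return image, truth


# ------------------------------------------------------------------ lipidomes
# Default composition: (number of species, class share of total mol%).
# Shares follow a typical cultured mammalian cell; the lysoGPL classes sum to
# ~0.55 mol% so the planted treatment effect roughly doubles them.
DEFAULT_CLASS_COMPOSITION: dict[str, tuple[int, float]] = {
    "PC": (40, 36.0), "PE": (35, 11.0), "PI": (18, 5.0), "PS": (18, 4.0),
    "PG": (10, 1.0), "PA": (10, 1.0), "PC O-": (16, 3.0), "PE O-": (16, 3.5),
    "LPC": (8, 0.25), "LPE": (6, 0.12), "LPA": (4, 0.03), "LPG": (4, 0.03),
    "LPI": (4, 0.04), "LPS": (4, 0.03), "LPC O-": (4, 0.03), "LPE O-": (4, 0.02),
    "SM": (25, 8.5), "Cer": (12, 1.2), "HexCer": (8, 0.5),
    "DAG": (12, 1.75), "BMP": (6, 0.5), "Chol": (1, 21.0), "CE": (8, 2.0),
}

# Planted effects per treated group: class/category-wide log2 fold changes
# plus a double-bond slope rule ("<category>:db": per-double-bond log2 shift
# relative to the category's baseline mean) that lowers mean unsaturation.
DEFAULT_PLANTED_EFFECTS: dict[str, list[tuple[str, float]]] = {
    "UA": [("lysoGPL", 0.95), ("SM", 0.30), ("Cer", -0.40), ("diacylGPL:db", -0.12)],
    "ebastine": [("lysoGPL", 0.40), ("SM", 0.25), ("Cer", -0.35)],
}


@dataclass
class LipidSimParams:
    """Design and noise model for the lipidome generator.

    The default replicate structure is the study design the statistics
    assume: three treatment groups measured as triplicates in each of three
    independent experiments (batches), i.e. nine data points per group.
    """

    groups: tuple[str, ...] = ("vehicle", "UA", "ebastine")
    n_batches: int = 3
    n_replicates: int = 3
    classes: dict[str, tuple[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COMPOSITION)
    )
    baseline_sigma: float = 0.8
    total_mol: float = 1000.0
    planted_effects: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {g: list(r) for g, r in DEFAULT_PLANTED_EFFECTS.items()}
    )
    n_subthreshold: int = 3
    subthreshold_molpct: float = 0.00002
    batch_log2_sd: float = 0.25
    noise_cv: float = 0.1
    is_amount: float = 20.0
    response_per_mol: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.n_replicates < 1:
            raise ValueError("replicate structure must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.total_mol <= 0 or self.baseline_sigma < 0:
            raise ValueError("baseline parameters must be positive")
        for cls, (n, pct) in self.classes.items():
            if n < 1 or pct <= 0:
                raise ValueError(f"class {cls!r} needs n_species >= 1 and share > 0")
        unknown = [g for g in self.planted_effects if g not in self.groups]
        if unknown:
            raise ValueError(f"planted effects for unknown groups {unknown}")


@dataclass
class LipidSimTruth:
    """Ground truth: per-species planted effects and noise-free quantities."""

    effects: pd.DataFrame  # species x group, planted log2 fold change
    baseline_mol: pd.Series  # noise/batch-free control quantities
    true_mol: pd.DataFrame  # species x sample, batch applied, noise-free
    subthreshold_species: list[str]


_CHAIN_GRID = {
    "diacylGPL": [(c, d) for c in (30, 32, 34, 36, 38, 40) for d in range(7)],
    "lysoGPL": [(c, d) for c in (16, 18, 20, 22) for d in range(5)],
    "SL": [(c, d) for c in (30, 32, 34, 36, 38, 40, 42) for d in (0, 1, 2, 3)],
    "sterol": [(c, d) for c in (16, 18, 20, 22) for d in (0, 1, 2)],
    "other": [(c, d) for c in (32, 34, 36, 38) for d in range(5)],
}


def _make_species(cls: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
    if cls == "Chol":
        return pd.DataFrame(
            {"class": [cls], "carbons": [27], "double_bonds": [1]}, index=["Chol"]
        )
    grid = _CHAIN_GRID[lipid_category(cls)]
    if n > len(grid):
        raise ValueError(f"class {cls!r}: at most {len(grid)} distinct species")
    picks = rng.choice(len(grid), size=n, replace=False)
    rows = [grid[int(i)] for i in sorted(picks)]
    names = [f"{cls} {c}:{d}" for c, d in rows]
    return pd.DataFrame(
        {
            "class": cls,
            "carbons": [c for c, _ in rows],
            "double_bonds": [d for _, d in rows],
        },
        index=names,
    )


def generate_lipidome(
    params: LipidSimParams,
) -> tuple[LipidTable, LipidSimTruth]:
    """Draw a lipidome intensity table with planted effects and ground truth.

    Species quantity = baseline x 2^(planted log2FC for the sample's group)
    x per-species batch factor x log-normal measurement noise (mean 1, CV
    ``noise_cv``). Intensities are quantities times a per-sample instrument
    response, and per-class internal standards are spiked at ``is_amount``
    with the same response, so absolute quantification inverts exactly.
    """
    rng = np.random.default_rng(params.seed)

    species = pd.concat(
        [_make_species(cls, n, rng) for cls, (n, _) in params.classes.items()]
    )
    # within-class species weights: log-normal, normalized to the class share
    baseline = pd.Series(0.0, index=species.index)
    for cls, (n, pct) in params.classes.items():
        idx = species.index[species["class"] == cls]
        w = np.exp(rng.normal(0.0, params.baseline_sigma, size=len(idx)))
        baseline.loc[idx] = params.total_mol * (pct / 100.0) * w / w.sum()

    sub_names: list[str] = []
    if params.n_subthreshold > 0:
        host = [c for c in params.classes if lipid_category(c) == "diacylGPL"]
        for k in range(params.n_subthreshold):
            cls = host[k % len(host)]
            name = f"{cls} {42 + 2 * (k // len(host))}:{7 + k % 3}"
            sub_names.append(name)
            species.loc[name] = {"class": cls, "carbons": 42, "double_bonds": 7}
            baseline.loc[name] = params.total_mol * params.subthreshold_molpct / 100.0
    species = species.assign(category=species["class"].map(lipid_category))

    effects = pd.DataFrame(0.0, index=species.index, columns=list(params.groups))
    for group, rules in params.planted_effects.items():
        for target, value in rules:
            if target.endswith(":db"):
                cat = target[:-3]
                sel = species["category"] == cat
                db = species.loc[sel, "double_bonds"].astype(float)
                w = baseline[sel]
                mean_db = float((db * w).sum() / w.sum())
                effects.loc[sel, group] += value * (db - mean_db)
            elif target in params.classes:
                effects.loc[species["class"] == target, group] += value
            elif target in set(CLASS_CATEGORY.values()):
                effects.loc[species["category"] == target, group] += value
            else:
                raise ValueError(f"planted-effect target {target!r} is neither class nor category")

    sample_rows = []
    for g in params.groups:
        for b in range(1, params.n_batches + 1):
            for r in range(1, params.n_replicates + 1):
                sample_rows.append(
                    {"sample": f"{g}_b{b}_r{r}", "group": g, "batch": f"batch{b}",
                     "replicate": r}
                )
    samples = pd.DataFrame(sample_rows).set_index("sample")

    n_sp = len(species)
    batch_factor = {
        f"batch{b}": 2.0 ** rng.normal(0.0, params.batch_log2_sd, size=n_sp)
        if params.batch_log2_sd > 0
        else np.ones(n_sp)
        for b in range(1, params.n_batches + 1)
    }
    sigma_ln = np.sqrt(np.log1p(params.noise_cv**2))

    true_mol = pd.DataFrame(index=species.index, columns=samples.index, dtype=float)
    data = pd.DataFrame(index=species.index, columns=samples.index, dtype=float)
    is_int = pd.DataFrame(
        index=pd.Index(sorted(params.classes), name="class"),
        columns=samples.index,
        dtype=float,
    )
    for s, meta in samples.iterrows():
        mol = (
            baseline.to_numpy()
            * 2.0 ** effects[meta["group"]].to_numpy()
            * batch_factor[meta["batch"]]
        )
        true_mol[s] = mol
        if sigma_ln > 0:
            noise = np.exp(rng.normal(0.0, sigma_ln, size=n_sp) - sigma_ln**2 / 2)
        else:
            noise = np.ones(n_sp)
        response = params.response_per_mol * 2.0 ** rng.normal(0.0, 0.15)
        data[s] = mol * noise * response
        is_int[s] = params.is_amount * response

    table = LipidTable(
        data=data,
        species=species,
        samples=samples,
        unit="intensity",
        is_intensity=is_int,
        is_amount=pd.Series(params.is_amount, index=is_int.index),
        provenance={"seed": params.seed},
    )
    truth = LipidSimTruth(
        effects=effects,
        baseline_mol=baseline,
        true_mol=true_mol,
        subthreshold_species=sub_names,
    )
    return table, truth


# --------------------------------------------------------------------- plates
@dataclass
class PlateSimParams:
    """True signal models for the plate-table generator.

    ``treatments`` maps a treatment name to its true parameters:
    ``cytotoxicity_pct`` (true dead fraction, %), ``flux_decay_per_h``
    (exponential decay rate of the degradable flux reporter; the
    non-degradable mutant stays constant) and ``pi_positive_pct``.
    Only the assays named in ``assays`` are emitted.
    """

    treatments: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "vehicle": {"cytotoxicity_pct": 5.0, "flux_decay_per_h": 0.0},
            "UA": {"cytotoxicity_pct": 40.0, "flux_decay_per_h": 0.0},
            "rapamycin": {"cytotoxicity_pct": 6.0, "flux_decay_per_h": 0.05},
        }
    )
    assays: tuple[str, ...] = ("cytotoxicity", "flux")
    timepoints: tuple[float, ...] = tuple(float(t) for t in range(0, 22, 2))
    n_replicates: int = 3
    n_experiments: int = 3
    noise_sd: float = 0.0
    total_absorbance: float = 1.0
    luminescence_0: float = 1000.0
    pi_cells_per_slide: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) == 0:
            raise ValueError("at least one time point is required")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("time points must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_replicates < 1 or self.n_experiments < 1:
            raise ValueError("replicate structure must be >= 1")
        for name, spec in self.treatments.items():
            pct = spec.get("cytotoxicity_pct", 0.0)
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"treatment {name!r}: cytotoxicity must be in [0, 100]")
            pi = spec.get("pi_positive_pct", 0.0)
            if not 0.0 <= pi <= 100.0:
                raise ValueError(f"treatment {name!r}: PI percentage must be in [0, 100]")


def generate_plate(params: PlateSimParams) -> pd.DataFrame:
    """Long-format plate table: one row per well x time x assay readout.

    Noiseless mode reproduces the true signal models exactly: LDH medium and
    lysate absorbances split the total by the true cytotoxicity; the flux
    reporter pair decays as ``exp(-lambda t)`` against a constant mutant; PI
    counts follow the true positive fraction.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    well = 0
    for treat, spec in params.treatments.items():
        for e in range(1, params.n_experiments + 1):
            for r in range(1, params.n_replicates + 1):
                well += 1
                base = dict(
                    well=f"W{well:04d}", treatment=treat,
                    replicate=r, experiment=f"exp{e}",
                )
                if "cytotoxicity" in params.assays:
                    frac = spec.get("cytotoxicity_pct", 0.0) / 100.0
                    for t in params.timepoints:
                        med = params.total_absorbance * frac
                        lys = params.total_absorbance * (1.0 - frac)
                        if params.noise_sd > 0:
                            med += rng.normal(0.0, params.noise_sd)
                            lys += rng.normal(0.0, params.noise_sd)
                        rows.append({**base, "time_h": t, "assay": "LDH_medium", "value": max(med, 0.0)})
                        rows.append({**base, "time_h": t, "assay": "LDH_lysate", "value": max(lys, 0.0)})
                if "flux" in params.assays:
                    lam = spec.get("flux_decay_per_h", 0.0)
                    for t in params.timepoints:
                        wt = params.luminescence_0 * np.exp(-lam * t)
                        mut = params.luminescence_0
                        if params.noise_sd > 0:
                            wt += rng.normal(0.0, params.noise_sd)
                            mut += rng.normal(0.0, params.noise_sd)
                        rows.append({**base, "time_h": t, "assay": "luminescence_wt", "value": max(wt, 0.0)})
                        rows.append({**base, "time_h": t, "assay": "luminescence_mut", "value": max(mut, 0.0)})
                if "pi" in params.assays:
                    frac = spec.get("pi_positive_pct", 0.0) / 100.0
                    n_tot = params.pi_cells_per_slide
                    n_pos = (
                        int(rng.binomial(n_tot, frac))
                        if params.noise_sd > 0
                        else int(round(n_tot * frac))
                    )
                    rows.append({**base, "time_h": 0.0, "assay": "PI_positive", "value": n_pos})
                    rows.append({**base, "time_h": 0.0, "assay": "cell_total", "value": n_tot})
    return pd.DataFrame(
        rows,
        columns=["well", "treatment", "time_h", "assay", "value", "replicate", "experiment"],
    )
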