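"""Shotgun-lipidomics post-processing and statistics.

This module starts where spectral identification ends: it consumes a
species x sample intensity table with class annotations plus per-class
internal-standard (IS) intensities and spiked amounts, and provides

* absolute quantification against the class IS (unit response factor),
* mol% normalization (per-sample molar percentage of all monitored lipids),
* the low-abundance filter (median < 1e-4 mol% in every sample type),
* per-species / per-class differential abundance via a fixed-effects linear
  model (group + batch) with Benjamini-Hochberg correction,
* class/category aggregation and acyl double-bond (saturation) profiles,
* drug-uptake normalization (e.g. ebastine per mole of total lipid).

The linear model is ordinary least squares fit per species on the linear
mol% scale; the log2 fold change is taken from the fitted group means
averaged over batches, so for balanced designs a purely multiplicative batch
effect leaves the fold-change estimate untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "CLASS_CATEGORY",
    "lipid_category",
    "LipidTable",
    "quantify_absolute",
    "to_molpct",
    "filter_low_abundance",
    "differential_lipids",
    "aggregate_classes",
    "double_bond_profile",
    "drug_uptake",
]

# class -> category map. diacylGPL: two acyl/alkyl chains; lysoGPL: one.
# BMP and DAG sit outside the saturation categories, as do the sterols.
_DIACYL_GPL = ("PA", "PC", "PE", "PG", "PI", "PS", "PC O-", "PE O-")
_LYSO_GPL = ("LPA", "LPC", "LPE", "LPG", "LPI", "LPS", "LPC O-", "LPE O-")
_SPHINGO = ("Cer", "HexCer", "SM")
_STEROL = ("Chol", "CE")

CLASS_CATEGORY: dict[str, str] = {
    **{c: "diacylGPL" for c in _DIACYL_GPL},
    **{c: "lysoGPL" for c in _LYSO_GPL},
    **{c: "SL" for c in _SPHINGO},
    **{c: "sterol" for c in _STEROL},
    "BMP": "other",
    "DAG": "other",
}


def lipid_category(lipid_class: str) -> str:
    """Category of a lipid class; unknown classes map to ``"other"``."""
    return CLASS_CATEGORY.get(lipid_class, "other")


@dataclass
class LipidTable:
    """Species x sample table with annotations, metadata and standards.

    Attributes
    ----------
    data
        DataFrame of values (species rows x sample columns) in ``unit``
        ("intensity", "mol" or "mol%").
    species
        Per-species annotation indexed like ``data``: ``class``,
        ``category``, ``carbons``, ``double_bonds``.
    samples
        Per-sample metadata indexed by sample name: ``group``, ``batch``,
        ``replicate``.
    is_intensity, is_amount
        Internal-standard intensities (class x sample) and spiked amounts
        (per class, in the same molar unit as quantified output); only
        meaningful while ``unit == "intensity"``.
    """

    data: pd.DataFrame
    species: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "intensity"
    is_intensity: pd.DataFrame | None = None
    is_amount: pd.Series | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.species.index):
            raise ValueError("data and species annotation indexes differ")
        missing = [s for s in self.data.columns if s not in self.samples.index]
        if missing:
            raise ValueError(f"samples metadata missing for {missing}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("quantities must be non-negative")
        if "category" not in self.species.columns:
            self.species = self.species.assign(
                category=self.species["class"].map(lipid_category)
            )

    def copy(self) -> "LipidTable":
        return replace(
            self,
            data=self.data.copy(),
            species=self.species.copy(),
            samples=self.samples.copy(),
            is_intensity=None if self.is_intensity is None else self.is_intensity.copy(),
            is_amount=None if self.is_amount is None else self.is_amount.copy(),
            provenance=dict(self.provenance),
        )

    # ------------------------------------------------------------------ CSV
    def to_csv(self, species_path, samples_path) -> None:
        """Write the wide species table (IS rows flagged) + sample metadata."""
        table = pd.concat([self.species.drop(columns=["category"]), self.data], axis=1)
        table.insert(3, "is_internal_standard", False)
        table.insert(4, "is_amount", np.nan)
        if self.is_intensity is not None:
            rows = []
            for cls in self.is_intensity.index:
                row = {
                    "class": cls,
                    "carbons": np.nan,
                    "double_bonds": np.nan,
                    "is_internal_standard": True,
                    "is_amount": float(self.is_amount[cls]),
                }
                row.update(self.is_intensity.loc[cls].to_dict())
                rows.append(pd.Series(row, name=f"IS {cls}"))
            table = pd.concat([table, pd.DataFrame(rows)])
        table.index.name = "species"
        table.to_csv(species_path)
        self.samples.to_csv(samples_path, index_label="sample")

    @classmethod
    def from_csv(cls, species_path, samples_path, unit: str = "intensity") -> "LipidTable":
        table = pd.read_csv(species_path, index_col="species")
        samples = pd.read_csv(samples_path, index_col="sample")
        ann_cols = ["class", "carbons", "double_bonds", "is_internal_standard", "is_amount"]
        sample_cols = [c for c in table.columns if c not in ann_cols]
        is_rows = table["is_internal_standard"].fillna(False).astype(bool)
        species = table.loc[~is_rows, ["class", "carbons", "double_bonds"]]
        data = table.loc[~is_rows, sample_cols].astype(float)
        is_intensity = is_amount = None
        if is_rows.any():
            is_intensity = table.loc[is_rows, sample_cols].astype(float).set_axis(
                table.loc[is_rows, "class"], axis=0
            )
            is_amount = table.loc[is_rows].set_index("class")["is_amount"].astype(float)
        return cls(
            data=data,
            species=species,
            samples=samples,
            unit=unit,
            is_intensity=is_intensity,
            is_amount=is_amount,
        )


def quantify_absolute(table: LipidTable) -> LipidTable:
    """Convert intensities to absolute molar quantities via the class IS.

    ``mol(species, sample) = intensity(species, sample) /
    intensity(IS_class, sample) * amount(IS_class)`` with a response factor
    of 1. Species whose class has no internal standard are excluded and
    listed in ``provenance["unquantified_species"]``.
    """
    if table.unit != "intensity":
        raise ValueError(f"expected an intensity table, got unit {table.unit!r}")
    if table.is_intensity is None or table.is_amount is None:
        raise ValueError("internal standards are required for absolute quantification")
    have_is = table.species["class"].isin(table.is_intensity.index)
    bad_is = [
        cls
        for cls in table.is_intensity.index
        if (table.is_intensity.loc[cls] <= 0).any() or table.is_amount[cls] <= 0
    ]
    if bad_is:
        raise ValueError(f"non-positive internal-standard values for classes {bad_is}")
    excluded = table.data.index[~have_is].tolist()
    data = table.data.loc[have_is]
    cls = table.species.loc[have_is, "class"]
    denom = table.is_intensity.loc[cls].set_axis(data.index, axis=0)
    amount = table.is_amount.loc[cls].set_axis(data.index)
    mol = data.div(denom).mul(amount, axis=0)
    prov = dict(table.provenance)
    prov["unquantified_species"] = excluded
    return LipidTable(
        data=mol,
        species=table.species.loc[have_is].copy(),
        samples=table.samples.copy(),
        unit="mol",
        provenance=prov,
    )


def to_molpct(table: LipidTable) -> LipidTable:
    """Express each species as a molar percentage of its sample's total.

    Internal standards never enter the total (they are carried separately);
    every output column sums to 100. An all-zero sample is an error.
    """
    if table.unit not in ("mol", "mol%"):
        raise ValueError("to_molpct needs molar quantities; run quantify_absolute first")
    totals = table.data.sum(axis=0)
    dead = totals[totals <= 0].index.tolist()
    if dead:
        raise ValueError(f"sample(s) with zero total lipid: {dead}")
    out = table.copy()
    out.data = table.data.div(totals, axis=1) * 100.0
    out.unit = "mol%"
    return out


def filter_low_abundance(
    table: LipidTable, threshold: float = 0.0001, group_col: str = "group"
) -> tuple[LipidTable, list[str]]:
    """Drop species below ``threshold`` mol% in every sample type.

    A species is retained iff its median mol% across the replicates of at
    least one sample type (treatment group) reaches the threshold. Returns
    the filtered table and the removal log. Idempotent and monotone in the
    threshold.
    """
    if table.unit != "mol%":
        raise ValueError("filter operates on mol% tables")
    groups = table.samples.loc[table.data.columns, group_col]
    medians = table.data.T.groupby(groups.to_numpy()).median().T
    keep = (medians >= threshold).any(axis=1)
    removed = table.data.index[~keep].tolist()
    out = table.copy()
    out.data = table.data.loc[keep]
    out.species = table.species.loc[keep]
    out.provenance = dict(table.provenance)
    out.provenance.setdefault("filtered_species", []).extend(removed)
    return out, removed


def _design_matrix(samples: pd.DataFrame, group_col, batch_col, reference, comparison):
    """Intercept + comparison indicator + batch dummies (first batch ref)."""
    groups = samples[group_col]
    ind = (groups == comparison).to_numpy(dtype=float)
    batches = pd.Categorical(samples[batch_col])
    cols = {"intercept": np.ones(len(samples)), f"group[{comparison}]": ind}
    for b in batches.categories[1:]:
        cols[f"batch[{b}]"] = (samples[batch_col] == b).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=samples.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}): "
            f"factors {group_col!r} and {batch_col!r} are confounded"
        )
    return X, batches.categories


def differential_lipids(
    table: LipidTable,
    reference: str,
    comparison: str,
    group_col: str = "group",
    batch_col: str = "batch",
    log_scale: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species differential abundance between two treatment groups.

    Fits ``quantity ~ group + batch`` (fixed effects, OLS) per species on the
    samples of the two groups; the p-value comes from the t-test of the group
    contrast, q-values from Benjamini-Hochberg across all species tested, and
    the log2 fold change from the ratio of fitted group means averaged over
    batches (``log_scale=True`` instead fits log2 quantities and reads the
    fold change off the group coefficient). A species is flagged significant
    when ``q < alpha``. Requires >= 2 replicates per group.
    """
    if table.unit not in ("mol", "mol%"):
        raise ValueError("differential_lipids needs quantified data")
    meta = table.samples.loc[table.data.columns]
    sel = meta[group_col].isin([reference, comparison])
    meta = meta[sel]
    for g in (reference, comparison):
        n_g = int((meta[group_col] == g).sum())
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} replicates; need >= 2")
    X, _ = _design_matrix(meta, group_col, batch_col, reference, comparison)
    Y = table.data[meta.index].to_numpy(dtype=float)
    if log_scale:
        if (Y <= 0).any():
            raise ValueError("log-scale fit requires strictly positive quantities")
        Y = np.log2(Y)
    Xm = X.to_numpy()
    n, p = Xm.shape
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    hat = xtx_inv @ Xm.T                      # p x n
    B = Y @ hat.T                             # species x p
    resid = Y - B @ Xm.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    c = np.zeros(p)
    c[1] = 1.0                                # the group contrast
    var_c = float(c @ xtx_inv @ c)
    se = np.sqrt(np.maximum(sigma2 * var_c, 0.0))
    coef = B[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, coef / np.where(se > 0, se, 1.0), np.sign(coef) * np.inf)
    tstat = np.where((se == 0) & (coef == 0), 0.0, tstat)
    pvals = np.where(
        np.isinf(tstat), 0.0, 2.0 * sps.t.sf(np.abs(np.where(np.isinf(tstat), 0, tstat)), dof)
    )
    pvals = np.where((se == 0) & (coef == 0), 1.0, pvals)

    # fitted group means, averaged over batches (balanced-design safe)
    def fitted_mean(group_value: float) -> np.ndarray:
        grid = X.copy()
        grid[f"group[{comparison}]"] = group_value
        return (B @ grid.to_numpy().T).mean(axis=1)

    mean_ref = fitted_mean(0.0)
    mean_comp = fitted_mean(1.0)
    if log_scale:
        log2fc = coef
        mean_ref, mean_comp = 2.0**mean_ref, 2.0**mean_comp
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.where(
                (mean_ref > 0) & (mean_comp > 0),
                np.log2(np.where(mean_comp > 0, mean_comp, 1.0))
                - np.log2(np.where(mean_ref > 0, mean_ref, 1.0)),
                np.nan,
            )
    q = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_ref": mean_ref,
            "mean_comp": mean_comp,
            "t": tstat,
            "df": float(dof),
            "pvalue": pvals,
            "qvalue": q,
            "significant": q < alpha,
        },
        index=table.data.index,
    )
    out.attrs["model"] = {
        "formula": f"quantity ~ {group_col} + {batch_col}",
        "scale": "log2" if log_scale else "linear",
        "log2fc_from": "group coefficient" if log_scale else "fitted group means",
        "reference": reference,
        "comparison": comparison,
    }
    return out


def aggregate_classes(table: LipidTable, level: str = "class") -> LipidTable:
    """Sum species mol% into class- or category-level rows.

    ``level`` is ``"class"`` or ``"category"``. Classes partition the
    species, so class mol% columns still sum to 100. The result is itself a
    :class:`LipidTable` (one row per class) so class-level differential
    analysis is just :func:`differential_lipids` on the aggregate.
    """
    if level not in ("class", "category"):
        raise ValueError("level must be 'class' or 'category'")
    if table.unit not in ("mol", "mol%"):
        raise ValueError("aggregate_classes needs quantified data")
    agg = table.data.groupby(table.species[level].to_numpy()).sum()
    agg.index.name = level
    if level == "class":
        ann = pd.DataFrame(
            {
                "class": agg.index,
                "category": [lipid_category(c) for c in agg.index],
                "carbons": np.nan,
                "double_bonds": np.nan,
            },
            index=agg.index,
        )
    else:
        ann = pd.DataFrame(
            {
                "class": agg.index,
                "category": agg.index,
                "carbons": np.nan,
                "double_bonds": np.nan,
            },
            index=agg.index,
        )
    return LipidTable(
        data=agg,
        species=ann,
        samples=table.samples.copy(),
        unit=table.unit,
        provenance=dict(table.provenance),
    )


def double_bond_profile(
    table: LipidTable, category: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Saturation profile of one lipid category.

    Returns ``(distribution, mean_db)``: ``distribution`` gives, per sample,
    the percentage of the category's total mol% carried by species with each
    total acyl double-bond count; ``mean_db`` is the mol%-weighted average
    number of double bonds per lipid in that category.
    """
    sel = table.species["category"] == category
    if not sel.any():
        raise ValueError(f"no species in category {category!r}")
    data = table.data.loc[sel]
    db = table.species.loc[sel, "double_bonds"].astype(int)
    totals = data.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(f"category {category!r} has zero abundance in some sample")
    dist = data.groupby(db.to_numpy()).sum().div(totals, axis=1) * 100.0
    dist.index.name = "double_bonds"
    mean_db = (data.mul(db, axis=0).sum(axis=0) / totals).rename("mean_double_bonds")
    return dist, mean_db


def drug_uptake(
    drug_intensity, drug_is_intensity, drug_is_amount: float, total_lipid_mol
) -> pd.Series:
    """Cellular drug uptake normalized to total lipid content.

    ``uptake = (drug_intensity / IS_intensity) * IS_amount / total_lipid``
    (mol drug per mol lipid). Zero IS intensity or zero lipid total yields
    NaN. All per-sample inputs may be Series aligned on sample names.
    """
    drug = pd.Series(drug_intensity, dtype=float)
    is_int = pd.Series(drug_is_intensity, dtype=float)
    total = pd.Series(total_lipid_mol, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        amount = np.where(is_int > 0, drug / is_int.where(is_int > 0, 1.0) * drug_is_amount, np.nan)
        uptake = np.where(total > 0, amount / total.where(total > 0, 1.0), np.nan)
    return pd.Series(uptake, index=drug.index, name="uptake")
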