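"""From individual brains to species-level traits.

Volumetric input is a long table with one row per (species, specimen,
neuropil, side) and a raw volume in cubic micrometers.  The pipeline
collapses it in three steps: paired neuropils are summed across
hemispheres, specimens are aggregated into species means (and SDs), and
every mean is normalized to a per-species reference volume — the summed
"undefined" central-brain regions, chosen as the allometric control
because none of the analysed neuropils contributes to it.

Species means are computed on raw volumes and logged later for
regression (mean-then-log); a geometric-mean alternative is available
for sensitivity analysis.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import normalize_label

__all__ = [
    "SpeciesTraitMatrix",
    "read_volume_table",
    "read_ecology_table",
    "sum_paired",
    "species_aggregate",
    "reference_volume",
    "relative_volumes",
    "variability_report",
    "check_species_alignment",
    "SpeciesMismatchError",
]

VOLUME_COLUMNS = ["species", "specimen", "neuropil", "side", "volume"]
SIDES = {"left", "right", "unpaired"}


class SpeciesMismatchError(ValueError):
    """Species sets of tree, volume table and ecology table disagree."""


@dataclass
class SpeciesTraitMatrix:
    """Species x neuropil summary of a volume table.

    ``mean``, ``sd`` and ``n`` are aligned DataFrames (species rows,
    neuropil columns); ``sd`` is the n-1 sample SD and is missing where
    only one specimen exists.  ``reference`` is the per-species
    reference volume and ``relative`` the mean matrix divided by it,
    both absent until :func:`reference_volume` / :func:`relative_volumes`
    have been applied.
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame
    reference: pd.Series | None = None
    relative: pd.DataFrame | None = None

    @property
    def missing(self) -> pd.DataFrame:
        return self.mean.isna()

    @property
    def species(self) -> list[str]:
        return list(self.mean.index)

    @property
    def neuropils(self) -> list[str]:
        return list(self.mean.columns)


def _read_table(path_or_buf, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    return df


def read_volume_table(path_or_buf) -> pd.DataFrame:
    """Read a delimited (comma or tab, auto-detected) volume table."""
    df = _read_table(path_or_buf, VOLUME_COLUMNS)[VOLUME_COLUMNS]
    df["species"] = df["species"].map(normalize_label)
    df["side"] = df["side"].str.strip().str.lower()
    validate_volume_table(df)
    return df


def read_ecology_table(path_or_buf) -> pd.DataFrame:
    """Read a delimited ecology table (species, activity, migration[, wingspan])."""
    df = _read_table(path_or_buf, ["species", "activity", "migration"])
    df["species"] = df["species"].map(normalize_label)
    for col, levels in [("activity", {"diurnal", "nocturnal"}),
                        ("migration", {"migratory", "non-migratory"})]:
        df[col] = df[col].str.strip().str.lower()
        bad = set(df[col]) - levels
        if bad:
            raise ValueError(f"{col} must be one of {sorted(levels)}, got {sorted(bad)}")
    if df["species"].duplicated().any():
        dupes = sorted(df.loc[df["species"].duplicated(), "species"])
        raise ValueError(f"duplicate species in ecology table: {dupes}")
    return df


def validate_volume_table(vt: pd.DataFrame) -> None:
    if not np.isfinite(vt["volume"]).all() or (vt["volume"] <= 0).any():
        bad = vt.loc[~np.isfinite(vt["volume"]) | (vt["volume"] <= 0)]
        raise ValueError(f"volumes must be finite and > 0; offending rows:\n{bad.head()}")
    bad_side = set(vt["side"]) - SIDES
    if bad_side:
        raise ValueError(f"side must be in {sorted(SIDES)}, got {sorted(bad_side)}")
    key = ["species", "specimen", "neuropil", "side"]
    if vt.duplicated(subset=key).any():
        dupes = vt.loc[vt.duplicated(subset=key), key]
        raise ValueError(f"duplicate (species, specimen, neuropil, side) rows:\n{dupes.head()}")


def sum_paired(vt: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Sum left and right hemispheres into one total volume per neuropil.

    Unpaired records pass through unchanged.  A paired neuropil present
    on a single side is an error in strict mode and a warned-about
    single-side total otherwise.
    """
    validate_volume_table(vt)
    mixed = vt.groupby(["species", "specimen", "neuropil"])["side"].agg(
        lambda s: "unpaired" in set(s) and len(set(s)) > 1
    )
    if mixed.any():
        raise ValueError(
            f"neuropils recorded both as unpaired and sided: "
            f"{mixed[mixed].index.tolist()[:5]}"
        )
    one_sided = vt[vt["side"].isin({"left", "right"})].groupby(
        ["species", "specimen", "neuropil"]
    )["side"].nunique()
    lonely = one_sided[one_sided < 2]
    if len(lonely):
        msg = f"paired neuropils with a single side: {lonely.index.tolist()[:5]}"
        if strict:
            raise ValueError(msg + " (pass strict=False to keep the single side)")
        warnings.warn(msg, stacklevel=2)
    out = (
        vt.groupby(["species", "specimen", "neuropil"], as_index=False)["volume"]
        .sum()
    )
    return out


def species_aggregate(summed: pd.DataFrame, method: str = "arithmetic") -> SpeciesTraitMatrix:
    """Collapse specimens into per-species mean and SD per neuropil.

    ``method="arithmetic"`` (default) averages raw volumes;
    ``"geometric"`` exponentiates the mean log volume (SD is then the
    log-scale SD).  Cells with a single specimen get a missing SD; cells
    with no specimen are missing entirely.
    """
    if method not in {"arithmetic", "geometric"}:
        raise ValueError("method must be 'arithmetic' or 'geometric'")
    df = summed.copy()
    if method == "geometric":
        df["volume"] = np.log(df["volume"])
    g = df.groupby(["species", "neuropil"])["volume"]
    mean = g.mean().unstack()
    sd = g.std(ddof=1).unstack()
    n = g.size().unstack().fillna(0).astype(int)
    if method == "geometric":
        mean = np.exp(mean)
    return SpeciesTraitMatrix(mean=mean, sd=sd.reindex_like(mean), n=n.reindex_like(mean).fillna(0).astype(int))


def reference_volume(
    summed: pd.DataFrame,
    reference_regions,
    strict: bool = True,
) -> pd.Series:
    """Per-species reference volume from the undefined central-brain regions.

    Each specimen's reference is the sum of the listed regions; the
    species reference is the mean over its specimens.  In strict mode a
    specimen lacking any listed region is an error.
    """
    regions = list(reference_regions)
    if not regions:
        raise ValueError("reference region list is empty")
    sub = summed[summed["neuropil"].isin(regions)]
    per_specimen = sub.pivot_table(
        index=["species", "specimen"], columns="neuropil", values="volume"
    ).reindex(columns=regions)
    if per_specimen.empty:
        raise ValueError(f"no reference regions {regions} found in table")
    if per_specimen.isna().any().any():
        holes = per_specimen[per_specimen.isna().any(axis=1)]
        msg = f"specimens missing reference regions:\n{holes[holes.isna().any(axis=1)].index.tolist()[:5]}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    per_specimen_sum = per_specimen.sum(axis=1, skipna=not strict)
    ref = per_specimen_sum.groupby("species").mean()
    ref.name = "reference_volume"
    return ref


def relative_volumes(stm: SpeciesTraitMatrix, reference: pd.Series) -> SpeciesTraitMatrix:
    """Attach the reference and the mean/reference relative-volume matrix."""
    missing = set(stm.species) - set(reference.index)
    if missing:
        raise ValueError(f"no reference volume for species: {sorted(missing)}")
    ref = reference.reindex(stm.mean.index)
    if (ref <= 0).any() or ref.isna().any():
        raise ValueError("reference volumes must be positive and present for all species")
    stm.reference = ref
    stm.relative = stm.mean.div(ref, axis=0)
    return stm


def variability_report(summed: pd.DataFrame) -> pd.DataFrame:
    """Within- vs between-species dispersion per neuropil.

    For each neuropil: the mean within-species coefficient of variation
    of raw volumes (over species with >= 2 specimens), the
    between-species CV of species means, the corresponding log-scale
    SDs, and the inter/intra ratio of log-scale SDs.  The PGLS machinery
    assumes this ratio is large; the study design expects at least an
    order of magnitude.
    """
    rows = []
    for neuropil, grp in summed.groupby("neuropil"):
        by_sp = grp.groupby("species")["volume"]
        means = by_sp.mean()
        intra_cv = (by_sp.std(ddof=1) / by_sp.mean()).dropna()
        intra_log_sd = grp.assign(lv=np.log(grp["volume"])).groupby("species")["lv"].std(ddof=1).dropna()
        inter_cv = means.std(ddof=1) / means.mean() if len(means) > 1 else np.nan
        inter_log_sd = np.log(means).std(ddof=1) if len(means) > 1 else np.nan
        intra = intra_log_sd.mean() if len(intra_log_sd) else np.nan
        rows.append(
            {
                "neuropil": neuropil,
                "intra_cv": intra_cv.mean() if len(intra_cv) else np.nan,
                "inter_cv": inter_cv,
                "intra_log_sd": intra,
                "inter_log_sd": inter_log_sd,
                "ratio": inter_log_sd / intra if intra and np.isfinite(intra) and intra > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("neuropil")


def overall_variability_ratio(summed: pd.DataFrame) -> float:
    """Dataset-level inter/intra variability ratio.

    The mean across neuropils of the between-species log-scale SD,
    divided by the mean across neuropils of the within-species
    log-scale SD — the single number summarizing whether species
    differences dominate individual differences across the whole brain.
    """
    rep = variability_report(summed)
    return float(rep["inter_log_sd"].mean() / rep["intra_log_sd"].mean())


def check_species_alignment(
    tree_labels,
    volume_species,
    ecology_species,
) -> list[str]:
    """Exact species matching across inputs after label normalization.

    Returns the sorted common species list; raises
    :class:`SpeciesMismatchError` naming every offender if the volume
    table contains species absent from the tree or the ecology table.
    """
    tree_set = {normalize_label(s) for s in tree_labels}
    vol_set = {normalize_label(s) for s in volume_species}
    eco_set = {normalize_label(s) for s in ecology_species}
    problems = []
    no_tree = sorted(vol_set - tree_set)
    if no_tree:
        problems.append(f"species in volume table but not in tree: {no_tree}")
    no_eco = sorted(vol_set - eco_set)
    if no_eco:
        problems.append(f"species in volume table but not in ecology table: {no_eco}")
    if problems:
        raise SpeciesMismatchError("; ".join(problems))
    return sorted(vol_set)
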