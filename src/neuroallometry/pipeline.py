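"""End-to-end orchestration of the comparative volumetric analysis.

``run_pipeline`` takes a tree, an individual-level volume table and an
ecology table and produces the full report bundle: the intra- vs
inter-species variability check, per-neuropil phylogenetic signal,
isometry (slope-index) and grade-shift tables for both ecological
factors, the pairwise slope matrix with its distance matrix and
dendrogram, a leverage report, the two-factor robustness model, the
optional brain-vs-wingspan regression, and a machine-readable manifest.
``run_all`` is the file-based wrapper used by the command line.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import (
    ConfoundedFactorsError,
    grade_shift_report,
    isometry_report,
    leverage_screen,
    pgls_fit,
    slope_index,
    two_factor_pgls,
)
from .clusters import hcluster, pairwise_slopes, to_distance
from .signal import signal_table
from .tree import PhyloTree, normalize_label
from .volumetrics import (
    check_species_alignment,
    read_ecology_table,
    read_volume_table,
    reference_volume,
    relative_volumes,
    species_aggregate,
    sum_paired,
)
from .simulate import DEFAULT_REFERENCE_REGIONS

__all__ = ["RunConfig", "run_pipeline", "run_all", "wingspan_allometry"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run; YAML-serializable."""

    tree_path: str | None = None
    volumes_path: str | None = None
    ecology_path: str | None = None
    output_dir: str = "neuroallometry_out"
    reference_regions: list[str] = field(
        default_factory=lambda: list(DEFAULT_REFERENCE_REGIONS)
    )
    excluded_neuropils: list[str] = field(default_factory=lambda: ["lamina"])
    #: neuropil -> species to drop for that neuropil only (e.g. a species
    #: whose mushroom-body lobes could not be delineated)
    excluded_species: dict[str, list[str]] = field(default_factory=dict)
    b0: float = 1.0            # isometric null, volume vs volume
    b0_wingspan: float = 3.0   # isometric null, volume vs length
    alpha: float = 0.05
    n_perm: int = 10_000
    n_sim: int = 10_000
    seed: int = 0
    linkage: str = "average"
    inclusion_r2: float = 0.6
    mean_method: str = "arithmetic"
    strict_pairing: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_traits(tree, volumes, ecology, cfg):
    """Shared front end: alignment, pairing, aggregation, normalization."""
    check_species_alignment(tree.tip_labels, volumes["species"], ecology["species"])
    summed = sum_paired(volumes, strict=cfg.strict_pairing)
    summed = summed[~summed["neuropil"].isin(cfg.excluded_neuropils)]
    ref = reference_volume(summed, cfg.reference_regions)
    defined = summed[~summed["neuropil"].isin(cfg.reference_regions)]
    stm = species_aggregate(defined, method=cfg.mean_method)
    stm = relative_volumes(stm, ref)
    for neuropil, drop in cfg.excluded_species.items():
        if neuropil in stm.mean.columns:
            sp = [normalize_label(s) for s in drop]
            stm.mean.loc[stm.mean.index.isin(sp), neuropil] = np.nan
            stm.relative.loc[stm.relative.index.isin(sp), neuropil] = np.nan
    return summed, stm


def wingspan_allometry(tree, volumes, ecology, cfg: RunConfig) -> dict:
    """PGLS of log total brain volume on log wingspan.

    Total brain volume is the per-species mean of each specimen's summed
    neuropil volumes (defined plus undefined regions, minus the
    configured exclusions).  The slope is tested against the configured
    length-to-volume isometric null (default 3).
    """
    if "wingspan" not in ecology.columns or ecology["wingspan"].isna().all():
        raise ValueError("ecology table has no wingspan column")
    summed = sum_paired(volumes, strict=cfg.strict_pairing)
    summed = summed[~summed["neuropil"].isin(cfg.excluded_neuropils)]
    total = (
        summed.groupby(["species", "specimen"])["volume"].sum()
        .groupby("species").mean()
    )
    wing = ecology.set_index("species")["wingspan"].reindex(total.index)
    if wing.isna().any():
        raise ValueError(f"missing wingspan for: {sorted(wing[wing.isna()].index)}")
    y = np.log(total)
    y.name = "log_total_brain"
    X = pd.DataFrame({"intercept": 1.0, "log_x": np.log(wing)})
    fit = pgls_fit(y, X, tree.vcv())
    si = slope_index(fit, b0=cfg.b0_wingspan)
    return {"fit": fit, **si, "r2": fit.r2, "r2_adj": fit.r2_adj, "n": fit.n,
            "b0": cfg.b0_wingspan}


def run_pipeline(
    tree: PhyloTree,
    volumes: pd.DataFrame,
    ecology: pd.DataFrame,
    cfg: RunConfig | None = None,
) -> dict:
    """Run every analysis stage on in-memory inputs; returns the bundle."""
    cfg = cfg or RunConfig()
    from .volumetrics import variability_report  # local to keep import cheap

    summed, stm = _prepare_traits(tree, volumes, ecology, cfg)
    C = tree.vcv()
    eco = ecology.set_index("species")
    activity = eco["activity"]
    migration = eco["migration"]

    bundle: dict = {}
    bundle["variability"] = variability_report(summed)
    log10_rel = np.log10(stm.relative)
    bundle["signal"] = signal_table(
        tree, log10_rel, n_perm=cfg.n_perm, n_sim=cfg.n_sim,
        seed=cfg.seed, alpha=cfg.alpha,
    )
    bundle["isometry"] = isometry_report(
        stm.mean, stm.reference, C, b0=cfg.b0, alpha=cfg.alpha,
        include_r2=cfg.inclusion_r2,
    )
    for factor, groups, group1 in [
        ("activity", activity, "diurnal"),
        ("migration", migration, "migratory"),
    ]:
        bundle[f"gradeshift_{factor}"] = grade_shift_report(
            stm.mean, stm.reference, groups, C, group1=group1,
            alpha=cfg.alpha, include_r2=cfg.inclusion_r2, on_error="skip",
        )

    sm = pairwise_slopes(np.log(stm.relative), C)
    assoc, dist = to_distance(sm)
    clus = hcluster(dist, method=cfg.linkage)
    bundle["slope_matrix"] = sm.slopes
    bundle["association"] = assoc
    bundle["distance"] = dist
    bundle["dendrogram_newick"] = clus.to_newick()
    bundle["clusters"] = clus.flat(k=min(4, len(dist) - 1)).to_frame()

    # leverage screen on every isometry regression
    lev_rows = []
    logx = np.log(stm.reference)
    for col in stm.mean.columns:
        y = np.log(stm.mean[col].dropna())
        y.name = col
        fit = pgls_fit(y, pd.DataFrame({"intercept": 1.0, "log_x": logx}), C)
        lev = leverage_screen(fit)
        for sp, row in lev[lev["flagged"]].iterrows():
            lev_rows.append({"neuropil": col, "species": sp,
                             "leverage": row["leverage"]})
    bundle["leverage"] = pd.DataFrame(lev_rows, columns=["neuropil", "species", "leverage"])

    # two-factor robustness model
    tf_rows = []
    for col in stm.mean.columns:
        y = np.log(stm.mean[col].dropna())
        y.name = col
        try:
            _, tests = two_factor_pgls(y, logx, activity, migration, C,
                                       alpha=cfg.alpha)
        except (ConfoundedFactorsError, ValueError) as exc:
            tf_rows.append({"neuropil": col, "term": "error", "note": str(exc)})
            continue
        for term, row in tests.iterrows():
            tf_rows.append({"neuropil": col, "term": term, **row.to_dict()})
    bundle["two_factor"] = pd.DataFrame(tf_rows)

    if "wingspan" in ecology.columns and ecology["wingspan"].notna().all():
        ws = wingspan_allometry(tree, volumes, ecology, cfg)
        bundle["wingspan"] = pd.DataFrame(
            [{k: v for k, v in ws.items() if k != "fit"}]
        )

    bundle["manifest"] = {
        "package": "neuroallometry",
        "version": __version__,
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "n_species": len(stm.species),
        "n_neuropils": len(stm.neuropils),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.tsv", sep="\t")
        elif isinstance(obj, str):
            (out / f"{name}.nwk").write_text(obj + "\n")
        else:
            with open(out / f"{name}.json", "w") as fh:
                json.dump(obj, fh, indent=2, default=str)


def run_all(cfg: RunConfig) -> dict:
    """Load the configured input files, run the pipeline, write the bundle."""
    for attr in ("tree_path", "volumes_path", "ecology_path"):
        path = getattr(cfg, attr)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"{attr} = {path!r} does not exist")
    tree = PhyloTree.from_newick(Path(cfg.tree_path).read_text())
    tree = tree.substitute_tips(
        {lbl: normalize_label(lbl) for lbl in tree.tip_labels
         if lbl != normalize_label(lbl)}
    ) if any(lbl != normalize_label(lbl) for lbl in tree.tip_labels) else tree
    volumes = read_volume_table(cfg.volumes_path)
    ecology = read_ecology_table(cfg.ecology_path)
    bundle = run_pipeline(tree, volumes, ecology, cfg)
    write_bundle(bundle, cfg.output_dir)
    return bundle
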