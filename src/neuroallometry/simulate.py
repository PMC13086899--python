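"""Synthetic phylogenies and neuropil-volume datasets.

The generator produces data with the statistical structure the analysis
pipeline assumes, so that every stage — aggregation, phylogenetic
signal, PGLS allometry, grade shifts, slope clustering — can be
exercised and its estimators validated against known ground truth:

* an ultrametric pure-birth phylogeny (depth normalized to 1);
* a per-species reference volume (the "central brain" allometric
  control) evolving by Brownian motion on the log scale;
* per-neuropil species mean volumes following the power law
  ``y = a * x**b`` with group-specific intercepts (grade shifts) and
  slopes, plus a Brownian phylogenetic residual;
* per-individual volumes with multiplicative within-species noise at
  least an order of magnitude below between-species variation;
* paired neuropils emitted as left/right halves summing to the
  individual total.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawns, so outputs are
bit-reproducible and per-neuropil streams are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "NeuropilSpec",
    "SimulationConfig",
    "simulate_tree",
    "simulate_bm",
    "simulate_species_traits",
    "simulate_dataset",
    "default_neuropil_specs",
    "DEFAULT_REFERENCE_REGIONS",
]

#: Undefined central-brain regions whose sum serves as the reference volume.
DEFAULT_REFERENCE_REGIONS = (
    "superior_np",
    "ventrolateral_np",
    "ventromedial_np",
    "inferior_np",
    "circumesophageal_np",
    "gnathal_np",
)


def simulate_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> PhyloTree:
    """Simulate a pure-birth (Yule) tree and rescale its depth to 1.

    Lineages split at exponentially distributed waiting times with total
    rate ``birth_rate * (number of extant lineages)``; the crown split
    happens at time zero, and after the last split the process runs for
    one more exponential waiting time before the present.  Rescaling the
    total depth to 1 makes Brownian rates comparable across tree sizes.
    Tips are labelled ``t1 .. tn``.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.is_rooted = True
    root = dtree.seed_node
    root.birth_time = 0.0
    active = []
    for _ in range(2):
        child = root.new_child()
        child.birth_time = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - node.birth_time
        for _ in range(2):
            child = node.new_child()
            child.birth_time = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.edge.length = t - node.birth_time
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"t{i}")
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    return PhyloTree(dtree)


def simulate_bm(
    tree: PhyloTree,
    sigma2: float,
    root_state: float,
    rng: np.random.Generator | int,
    size: int | None = None,
) -> np.ndarray:
    """Simulate Brownian-motion trait values at the tips of ``tree``.

    Each node's value is its parent's value plus a Normal(0,
    sigma2 * branch_length) increment.  Returns an array of tip values
    in ``tree.tip_labels`` order, of shape ``(n_tips,)`` or
    ``(size, n_tips)`` when ``size`` is given (independent replicates).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nrep = 1 if size is None else size
    dtree = tree._tree
    values = {dtree.seed_node: np.full(nrep, float(root_state))}
    tips = []
    for node in dtree.preorder_node_iter():
        if node is dtree.seed_node:
            continue
        sd = math.sqrt(sigma2 * node.edge.length)
        values[node] = values[node.parent_node] + rng.normal(0.0, sd, size=nrep)
        if node.is_leaf():
            tips.append(values[node])
    out = np.column_stack(tips)
    return out[0] if size is None else out


@dataclass(frozen=True)
class NeuropilSpec:
    """Generative parameters for one neuropil.

    ``intercept`` is log(a) on the natural-log scale and ``slope`` is the
    allometric exponent b; either may be a plain float (shared across
    species) or a mapping from an ecology level (``"diurnal"``,
    ``"nocturnal"``, ``"migratory"``, ``"non-migratory"``) to a value,
    which plants a grade shift or a slope difference along that axis.
    ``resid_sigma2`` is the Brownian rate of the phylogenetic residual
    around the allometric line.
    """

    name: str
    paired: bool = True
    intercept: float | dict[str, float] = 0.0
    slope: float | dict[str, float] = 1.0
    resid_sigma2: float = 0.03

    def _resolve(self, value, activity: str, migration: str) -> float:
        if isinstance(value, dict):
            for key in (activity, migration):
                if key in value:
                    return float(value[key])
            raise ValueError(
                f"{self.name}: no entry for activity={activity!r} or "
                f"migration={migration!r} in {value!r}"
            )
        return float(value)

    def params_for(self, activity: str, migration: str) -> tuple[float, float]:
        return (
            self._resolve(self.intercept, activity, migration),
            self._resolve(self.slope, activity, migration),
        )


def default_neuropil_specs() -> list[NeuropilSpec]:
    """Generative defaults for a lepidopteran-style neuropil inventory.

    Intercepts are natural logs of typical volume fractions relative to
    the central-brain reference.  Sensory neuropils carry an
    activity-period grade shift (visual regions larger in diurnal
    species, the antennal lobe larger in nocturnal ones); the
    fan-shaped body, accessory medulla and mushroom-body spur carry a
    migration grade shift; central-complex regions scale shallowly
    (b < 1); the gall has genuinely different slopes between activity
    groups.
    """

    def ln(x: float) -> float:
        return math.log(x)

    di, no = "diurnal", "nocturnal"
    mi, nm = "migratory", "non-migratory"
    return [
        NeuropilSpec("ME", True, {di: ln(0.90), no: ln(0.50)}, 1.0),
        NeuropilSpec("AME", True, {mi: ln(0.0045), nm: ln(0.0025)}, 1.0),
        NeuropilSpec("LO", True, {di: ln(0.28), no: ln(0.16)}, 1.0),
        NeuropilSpec("LOP", True, {di: ln(0.11), no: ln(0.06)}, 1.0),
        NeuropilSpec("AOTU_UU", True, {di: ln(0.016), no: ln(0.009)}, 1.0),
        NeuropilSpec("AOTU_LUC", True, ln(0.004), 0.9),
        NeuropilSpec("AL", True, {no: ln(0.14), di: ln(0.08)}, 1.0),
        NeuropilSpec("CA", True, ln(0.06), 1.1),
        NeuropilSpec("PED", True, ln(0.012), 1.0),
        NeuropilSpec("VL", True, ln(0.014), 1.0),
        NeuropilSpec("ML", True, ln(0.013), 1.0),
        NeuropilSpec("VGL", True, ln(0.004), 1.0),
        NeuropilSpec("MGL", True, ln(0.004), 1.0),
        NeuropilSpec("YL", True, {no: ln(0.009), di: ln(0.005)}, 1.0),
        NeuropilSpec("SPU", True, {mi: ln(0.003), nm: ln(0.0018)}, 1.0),
        NeuropilSpec("EB", False, ln(0.005), 0.7),
        NeuropilSpec("FB", False, {mi: ln(0.022), nm: ln(0.012)}, 1.0),
        NeuropilSpec("PB", True, ln(0.003), 0.8),
        NeuropilSpec("NO", True, ln(0.0012), 0.75),
        NeuropilSpec("LAL", True, ln(0.016), 0.8),
        NeuropilSpec("GA", True, ln(0.0008), {no: 1.4, di: 0.8}),
        NeuropilSpec("BU", True, ln(0.0012), 1.0, resid_sigma2=0.12),
        NeuropilSpec("OCN", True, ln(0.0006), 1.0),
        NeuropilSpec("POTU", True, ln(0.0005), 1.0),
    ]


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 15 species, 3 brains each, ~24 neuropils.

    ``sigma2_bm`` is the Brownian rate of the log reference volume per
    unit (normalized) branch length; ``intra_cv`` is the within-species
    coefficient of variation of raw volumes.  The defaults put
    between-species spread in log volume (~sqrt(0.5) = 0.71) more than
    an order of magnitude above within-species spread (~0.05).
    """

    n_species: int = 15
    individuals_per_species: int = 3
    sigma2_bm: float = 0.5
    root_state: float = math.log(5.0e6)  # log reference volume, micrometer^3
    ref_resid_sigma2: float = 0.02  # reference-volume BM deviation off the body-size line
    intra_cv: float = 0.05
    neuropils: list[NeuropilSpec] = field(default_factory=default_neuropil_specs)
    reference_regions: tuple[str, ...] = DEFAULT_REFERENCE_REGIONS
    n_diurnal: int | None = None  # default: half, rounded down
    n_migratory: int | None = None  # default: one third, at least 3
    tree: PhyloTree | None = None  # overrides the pure-birth simulation
    ecology: pd.DataFrame | None = None  # overrides the random assignment
    with_wingspan: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_bm < 0 or self.intra_cv < 0:
            raise ValueError("sigma2_bm and intra_cv must be >= 0")
        if self.individuals_per_species < 1:
            raise ValueError("individuals_per_species must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "neuropils" in d:
            d["neuropils"] = [
                np_ if isinstance(np_, NeuropilSpec) else NeuropilSpec(**np_)
                for np_ in d["neuropils"]
            ]
        return cls(**d)


def _assign_ecology(species: list[str], cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = len(species)
    n_di = cfg.n_diurnal if cfg.n_diurnal is not None else n // 2
    n_mi = cfg.n_migratory if cfg.n_migratory is not None else max(3, n // 3)
    if not (0 <= n_di <= n and 0 <= n_mi <= n):
        raise ValueError("group sizes exceed n_species")
    activity = np.array(["diurnal"] * n_di + ["nocturnal"] * (n - n_di))
    migration = np.array(["migratory"] * n_mi + ["non-migratory"] * (n - n_mi))
    rng.shuffle(activity)
    rng.shuffle(migration)
    return pd.DataFrame(
        {"species": species, "activity": activity, "migration": migration}
    )


def simulate_species_traits(
    tree: PhyloTree,
    spec: NeuropilSpec,
    log_reference: np.ndarray,
    ecology: pd.DataFrame,
    rng: np.random.Generator,
) -> np.ndarray:
    """Species-level log mean volumes for one neuropil.

    ``log a_g + b_g * log(x)`` per species, plus a Brownian residual
    simulated on the tree with rate ``spec.resid_sigma2``.
    """
    eco = ecology.set_index("species")
    la = np.empty(tree.n_tips)
    b = np.empty(tree.n_tips)
    for i, sp in enumerate(tree.tip_labels):
        row = eco.loc[sp]
        la[i], b[i] = spec.params_for(row["activity"], row["migration"])
    resid = simulate_bm(tree, spec.resid_sigma2, 0.0, rng)
    return la + b * log_reference + resid


def _individual_volumes(log_mean: float, n_ind: int, intra_cv: float,
                        rng: np.random.Generator) -> np.ndarray:
    mean = math.exp(log_mean)
    vols = mean * (1.0 + rng.normal(0.0, intra_cv, size=n_ind))
    while np.any(vols <= 0):  # truncate multiplicative noise at zero volume
        bad = vols <= 0
        vols[bad] = mean * (1.0 + rng.normal(0.0, intra_cv, size=int(bad.sum())))
    return vols


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[PhyloTree, pd.DataFrame, pd.DataFrame]:
    """Simulate a full study dataset.

    Returns ``(tree, volumes, ecology)`` where ``volumes`` is a long
    table with columns species / specimen / neuropil / side / volume
    (micrometer^3) covering the configured neuropils plus the undefined
    reference regions, and ``ecology`` maps species to activity period,
    migratory status and (optionally) wingspan in mm.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_eco, s_ref, s_np, s_noise, s_wing = ss.spawn(6)
    tree = cfg.tree or simulate_tree(cfg.n_species, seed=s_tree)
    species = tree.tip_labels

    if cfg.ecology is not None:
        ecology = cfg.ecology.copy()
        missing = set(species) - set(ecology["species"])
        if missing:
            raise ValueError(f"ecology table missing species: {sorted(missing)}")
    else:
        ecology = _assign_ecology(species, cfg, np.random.default_rng(s_eco))

    # body size (log wingspan deviation) evolves by BM and drives the
    # reference volume with the isometric volume-length exponent 3; the
    # reference keeps its own BM deviation off that line.  The two rates
    # sum to sigma2_bm, the total Brownian rate of the log reference.
    body_rate = max(cfg.sigma2_bm - cfg.ref_resid_sigma2, 0.0) / 9.0
    body = simulate_bm(tree, body_rate, 0.0, np.random.default_rng(s_wing))
    log_ref = (
        cfg.root_state
        + 3.0 * body
        + simulate_bm(tree, cfg.ref_resid_sigma2, 0.0, np.random.default_rng(s_ref))
    )

    noise_rng = np.random.default_rng(s_noise)
    n_ind = cfg.individuals_per_species
    records: list[tuple] = []

    def emit(sp: str, neuropil: str, paired: bool, vols: np.ndarray) -> None:
        for k, v in enumerate(vols, start=1):
            spec_id = f"{sp}_{k:02d}"
            if paired:
                f = float(np.clip(noise_rng.normal(0.5, 0.02), 0.3, 0.7))
                records.append((sp, spec_id, neuropil, "left", v * f))
                records.append((sp, spec_id, neuropil, "right", v * (1 - f)))
            else:
                records.append((sp, spec_id, neuropil, "unpaired", v))

    # defined neuropils: allometric in the reference volume
    np_rng = np.random.default_rng(s_np)
    for spec in cfg.neuropils:
        log_means = simulate_species_traits(tree, spec, log_ref, ecology, np_rng)
        for sp, lm in zip(species, log_means):
            emit(sp, spec.name, spec.paired, _individual_volumes(lm, n_ind, cfg.intra_cv, noise_rng))

    # undefined reference regions: species-level split of the reference volume
    ref_rng = np.random.default_rng(s_ref.spawn(1)[0])
    k = len(cfg.reference_regions)
    for sp, lx in zip(species, log_ref):
        props = ref_rng.dirichlet(np.full(k, 10.0))
        for region, p in zip(cfg.reference_regions, props):
            emit(sp, region, False, _individual_volumes(lx + math.log(p), n_ind, cfg.intra_cv, noise_rng))

    volumes = pd.DataFrame(records, columns=["species", "specimen", "neuropil", "side", "volume"])

    if cfg.with_wingspan:
        ecology = ecology.copy()
        ecology["wingspan"] = 40.0 * np.exp(body)  # mm, centred near a 40 mm span
    return tree, volumes, ecology
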