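"""Synthetic microcosm-experiment generator.

Emulates the statistical structure of a compounded-disturbance soil
microcosm study so the whole analysis chain can be exercised without raw
data: a control plus disturbance treatments (three repeated single
disturbances F/H/A and the six chronology orderings of the three), four
replicates, five sampling timepoints (T0..T4), ~26 functional/abundance
response variables with configurable true standardized effects, and OTU
count tables with treatment-dependent composition shifts on a random rooted
phylogeny.

Measurements: control replicates are i.i.d. Normal(mu_v, sd_v) per variable;
treated replicates are Normal(mu_v + delta * sd_v, sd_v) where delta is the
planted standardized effect for that (treatment, timepoint, variable) cell.
Noise is Normal on the analysis scale: variables configured for a log10
transform are drawn on the log scale and written back as 10**x, so the
analysis-side transform recovers the planted delta.

Communities: counts are Dirichlet-multinomial — per sample a composition is
drawn from Dirichlet(alpha) and counts from a Multinomial at a random depth;
a disturbance shifts the log-alpha of a configurable fraction of OTUs. This
is a minimal overdispersed count model supporting composition shifts, not a
mechanistic model of disturbance physiology.

Every generator is a pure function of its specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "VariableSpec",
    "ExperimentDesign",
    "CommunitySpec",
    "default_design",
    "chronology_treatments",
    "simulate_measurements",
    "random_tree",
    "simulate_communities",
]

#: the six orderings of Freeze-thaw (F), Heat (H) and Anoxia (A)
CHRONOLOGIES = ("FHA", "FAH", "HFA", "HAF", "AFH", "AHF")


@dataclass(frozen=True)
class VariableSpec:
    name: str
    baseline_mean: float
    baseline_sd: float
    transform: str = "none"  # none | log10


@dataclass(frozen=True)
class ExperimentDesign:
    treatments: tuple[str, ...]
    control: str
    timepoints: tuple[str, ...] = ("T0", "T1", "T2", "T3", "T4")
    n_replicates: int = 4
    variables: tuple[VariableSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.control not in self.treatments:
            raise ValueError(f"control {self.control!r} not among treatments")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for v in self.variables:
            if v.baseline_sd <= 0:
                raise ValueError(f"baseline_sd must be > 0 for {v.name!r}")
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ValueError("duplicate variable names in design")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def transform_map(self) -> dict[str, str]:
        return {v.name: v.transform for v in self.variables}


# EffectSpec: mapping (treatment, timepoint, variable) -> true standardized
# effect delta; absent keys mean delta = 0.
EffectSpec = Mapping[tuple[str, str, str], float]


@dataclass(frozen=True)
class CommunitySpec:
    n_otus: int = 300
    tree_seed: int = 7
    base_dirichlet_alpha: tuple[float, ...] | None = None
    #: total Dirichlet concentration; smaller = more replicate-to-replicate
    #: compositional noise (overdispersion)
    alpha_total: float = 50.0
    depth_range: tuple[int, int] = (2500, 5000)
    # (treatment, timepoint) -> (affected OTU fraction, log-fold alpha shift)
    shift: Mapping[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def alphas(self) -> np.ndarray:
        if self.base_dirichlet_alpha is not None:
            a = np.asarray(self.base_dirichlet_alpha, dtype=float)
            if a.size != self.n_otus or np.any(a <= 0):
                raise ValueError("base_dirichlet_alpha must be n_otus positive reals")
            return a
        if self.alpha_total <= 0:
            raise ValueError("alpha_total must be positive")
        rng = np.random.default_rng(self.tree_seed + 1)
        a = rng.lognormal(mean=0.0, sigma=1.5, size=self.n_otus)
        return a * (self.alpha_total / a.sum())


def _default_variables() -> tuple[VariableSpec, ...]:
    rates = [
        ("PNA", 5.0, 1.0),  # potential nitrification, ug N g-1 h-1
        ("PDA", 8.0, 1.5),  # potential denitrification, ug N g-1 h-1
        ("potential_N2O", 2.0, 0.5),
        ("N2O_ratio", 0.4, 0.1),
        ("nitrification_capacity", 3.0, 0.8),
        ("denitrification_capacity", 6.0, 1.2),
        ("respiration", 12.0, 2.0),
    ]
    pools = [
        ("NH4", 15.0, 3.0),  # ug N g-1 dry soil
        ("NO3", 40.0, 6.0),
        ("total_N", 2.5, 0.3),
        ("DOC", 120.0, 15.0),
        ("microbial_biomass_C", 300.0, 40.0),
        ("pH", 6.8, 0.15),
    ]
    # gene-copy abundances analysed on the log10 scale
    genes = [
        ("q16S", 9.5, 0.2),
        ("qAOA_amoA", 7.0, 0.25),
        ("qAOB_amoA", 6.5, 0.25),
        ("qnirK", 7.5, 0.2),
        ("qnirS", 7.2, 0.2),
        ("qnosZI", 7.0, 0.2),
        ("qnosZII", 6.8, 0.2),
    ]
    ratios = [
        ("AOA_AOB_ratio", 3.0, 0.6),
        ("nirK_nirS_ratio", 2.0, 0.4),
        ("nosZI_nosZII_ratio", 1.6, 0.3),
    ]
    diversity = [
        ("observed_species", 900.0, 60.0),
        ("faith_pd", 55.0, 4.0),
        ("simpson_reciprocal", 80.0, 8.0),
    ]
    out = [VariableSpec(n, m, s) for n, m, s in rates + pools]
    out += [VariableSpec(n, m, s, transform="log10") for n, m, s in genes]
    out += [VariableSpec(n, m, s) for n, m, s in ratios + diversity]
    return tuple(out)


def chronology_treatments() -> tuple[str, ...]:
    return CHRONOLOGIES


def default_design(
    n_replicates: int = 4,
    timepoints: Sequence[str] = ("T0", "T1", "T2", "T3", "T4"),
) -> ExperimentDesign:
    """The study-like design: 1 control, 3 repeated single disturbances
    (F, H, A), 6 chronology treatments, 4 replicates, 5 timepoints, 26
    response variables (gene abundances log10-transformed)."""
    return ExperimentDesign(
        treatments=("control", "F", "H", "A") + CHRONOLOGIES,
        control="control",
        timepoints=tuple(timepoints),
        n_replicates=n_replicates,
        variables=_default_variables(),
    )


def sample_id(treatment: str, timepoint: str, replicate: int) -> str:
    return f"{treatment}.{timepoint}.r{replicate}"


def simulate_measurements(
    design: ExperimentDesign, effects: EffectSpec, seed: int
) -> pd.DataFrame:
    """Long-format measurement table for a design with planted effects.

    Control cells always receive delta = 0. Deterministic given the seed.
    """
    if not design.variables:
        raise ValueError("design has no variables")
    rng = np.random.default_rng(seed)
    rows = []
    for treatment in design.treatments:
        for timepoint in design.timepoints:
            for var in design.variables:
                delta = 0.0
                if treatment != design.control:
                    delta = float(
                        effects.get((treatment, timepoint, var.name), 0.0)
                    )
                loc = var.baseline_mean + delta * var.baseline_sd
                draws = rng.normal(loc, var.baseline_sd, size=design.n_replicates)
                if var.transform == "log10":
                    draws = np.power(10.0, draws)
                for rep, value in enumerate(draws, start=1):
                    rows.append(
                        {
                            "sample_id": sample_id(treatment, timepoint, rep),
                            "treatment": treatment,
                            "timepoint": timepoint,
                            "replicate": rep,
                            "variable": var.name,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows)


def random_tree(n_leaves: int, seed: int) -> TreeNode:
    """Random bifurcating rooted tree built by successive random joins,
    branch lengths ~ Exponential(mean 0.1), leaves OTU_1..OTU_n."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(1, n_leaves + 1):
        leaf = TreeNode(name=f"OTU_{i}")
        leaf.length = float(rng.exponential(0.1))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(children=[left, right])
        parent.length = float(rng.exponential(0.1))
        nodes.append(parent)
    root = nodes[0]
    root.length = None  # the root has no branch above it
    return root


def simulate_communities(
    design: ExperimentDesign, spec: CommunitySpec, seed: int
) -> tuple[pd.DataFrame, TreeNode]:
    """Dirichlet-multinomial OTU counts per sample plus the phylogeny.

    Returns a samples x OTUs count table whose sample ids match
    :func:`simulate_measurements`, and the rooted tree whose leaves are the
    OTU ids. The affected-OTU set of each shifted (treatment, timepoint)
    cell is drawn once and shared by its replicates.
    """
    lo, hi = spec.depth_range
    if lo > hi or lo <= 0:
        raise ValueError("invalid depth_range")
    base_alpha = spec.alphas()
    tree = random_tree(spec.n_otus, spec.tree_seed)
    rng = np.random.default_rng(seed)

    cell_alpha: dict[tuple[str, str], np.ndarray] = {}
    for treatment in design.treatments:
        for timepoint in design.timepoints:
            alpha = base_alpha
            shift = spec.shift.get((treatment, timepoint))
            if shift is not None:
                frac, logfold = shift
                if not 0.0 <= frac <= 1.0:
                    raise ValueError("affected OTU fraction must be in [0, 1]")
                k = int(round(frac * spec.n_otus))
                affected = rng.choice(spec.n_otus, size=k, replace=False)
                alpha = base_alpha.copy()
                alpha[affected] *= np.exp(logfold)
            cell_alpha[(treatment, timepoint)] = alpha

    otu_ids = [f"OTU_{i}" for i in range(1, spec.n_otus + 1)]
    table = {}
    for treatment in design.treatments:
        for timepoint in design.timepoints:
            alpha = cell_alpha[(treatment, timepoint)]
            for rep in range(1, design.n_replicates + 1):
                depth = int(rng.integers(lo, hi + 1))
                p = rng.dirichlet(alpha)
                table[sample_id(treatment, timepoint, rep)] = rng.multinomial(
                    depth, p
                )
    profiles = pd.DataFrame.from_dict(table, orient="index", columns=otu_ids)
    return profiles, tree
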