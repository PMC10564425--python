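"""Synthetic cohort generator with planted ferroptosis signal structure.

The generator plants the three relationships the downstream pipeline is
designed to recover:

1. A latent per-sample ferroptosis activity ``f ~ N(0, 1)`` shifts positive
   ferroptosis-regulator genes up (+gamma * f) and negative regulators down
   (-gamma * f) on the log2 scale.
2. Each immune cell type owns a marker-gene block built as
   ``rho * f + sqrt(1 - rho^2) * noise``, so the block's shared component
   correlates with the latent factor at a controlled rho — B cells strongest
   by default.
3. Survival is exponential with hazard ``baseline_hazard * exp(-beta * f)``
   (higher ferroptosis activity -> lower hazard), censored by an independent
   Uniform(0, censor_horizon) time.

Background genes are pure noise.  A single root seed drives one generator
stream, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortAnnotations, ExpressionMatrix, GeneSet, GeneSetCollection, InputError
from .fpi import NEGATIVE_FRG, POSITIVE_FRG

__all__ = ["CohortConfig", "generate_cohort", "generate_toy_survival", "DEFAULT_RHO"]

# 24 immune cell types of the marker-based ssGSEA infiltration panel.  Default
# target correlations with the latent ferroptosis factor encode the expected
# ordering: B cells strongest, then CD8 T / T helper / Th17 / NK subsets,
# everything else weakly coupled.
DEFAULT_RHO: dict[str, float] = {
    "B cells": 0.70,
    "CD8 T cells": 0.50,
    "T helper cells": 0.45,
    "Th17 cells": 0.40,
    "NK CD56bright cells": 0.35,
    "NK CD56dim cells": 0.30,
    **{
        ct: 0.10
        for ct in (
            "aDC", "DC", "iDC", "pDC", "Eosinophils", "Macrophages", "Mast cells",
            "Neutrophils", "NK cells", "T cells", "Tcm", "Tem", "Tfh", "Tgd",
            "Th1 cells", "Th2 cells", "Treg", "Cytotoxic cells",
        )
    },
}


@dataclass
class CohortConfig:
    """Parameters of the planted-signal cohort.

    gamma is the log2 shift per unit latent factor on regulator genes; beta
    the log-hazard decrease per unit latent factor; baseline_hazard is in
    events/day and censor_horizon in days.
    """

    n_samples: int = 200
    n_background_genes: int = 300
    gamma: float = 1.0
    rho_by_celltype: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RHO))
    beta: float = 0.7
    baseline_hazard: float = 1.0 / 1000.0
    censor_horizon: float = 3000.0
    noise_sd: float = 1.0
    markers_per_celltype: int = 5
    group_effect: float = 0.0  # latent-factor shift of tumor vs normal samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise InputError("n_samples must be >= 4")
        if any(abs(r) >= 1 for r in self.rho_by_celltype.values()):
            raise InputError("all |rho| must be < 1")
        if self.noise_sd <= 0:
            raise InputError("noise_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise InputError("baseline_hazard must be > 0")
        if self.markers_per_celltype < 1:
            raise InputError("markers_per_celltype must be >= 1")


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, CohortAnnotations, GeneSetCollection]:
    """Generate (expression, annotations, gene sets) with the planted structure.

    Returned gene sets: FRG_positive, FRG_negative, and one marker set per
    immune cell type.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    f = rng.standard_normal(n)  # latent ferroptosis activity
    half = n // 2
    group = np.array(["tumor"] * half + ["normal"] * (n - half))
    f = f + np.where(group == "tumor", config.group_effect, 0.0)

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []

    def add_gene(name: str, mean_shift: np.ndarray) -> None:
        baseline = rng.uniform(2.0, 10.0)
        gene_rows.append(baseline + mean_shift + config.noise_sd * rng.standard_normal(n))
        gene_ids.append(name)

    for g in POSITIVE_FRG:
        add_gene(g, +config.gamma * f)
    for g in NEGATIVE_FRG:
        add_gene(g, -config.gamma * f)

    sets = [
        GeneSet("FRG_positive", "planted positive regulators", frozenset(POSITIVE_FRG)),
        GeneSet("FRG_negative", "planted negative regulators", frozenset(NEGATIVE_FRG)),
    ]

    for ct, rho in config.rho_by_celltype.items():
        tag = ct.replace(" ", "_")
        members = []
        for k in range(config.markers_per_celltype):
            name = f"MK_{tag}_{k}"
            shared = rho * f + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
            add_gene(name, config.noise_sd * shared)
            members.append(name)
        sets.append(GeneSet(ct, f"planted markers, rho={rho}", frozenset(members)))

    for i in range(config.n_background_genes):
        add_gene(f"BG_{i:05d}", np.zeros(n))

    expr = ExpressionMatrix(gene_ids, [f"S{j:04d}" for j in range(n)], np.vstack(gene_rows))

    hazard = config.baseline_hazard * np.exp(-config.beta * f)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_horizon, size=n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    ann = CohortAnnotations(
        pd.DataFrame(
            {
                "group": group,
                "time": np.maximum(time, 1e-6),
                "event": event,
                "latent_factor": f,
            },
            index=pd.Index(expr.sample_ids, name="sample_id"),
        )
    )
    return expr, ann, GeneSetCollection(sets)


def generate_toy_survival(
    n_per_group: int,
    seed: int,
    rate_ratio: float = 2.0,
    base_rate: float = 0.01,
    censor_horizon: float = 300.0,
) -> CohortAnnotations:
    """Two-group exponential survival fixture ("A" vs "B").

    Group B's event rate is ``base_rate * rate_ratio``; both groups are
    censored by independent Uniform(0, censor_horizon) times.
    """
    if n_per_group < 2:
        raise InputError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    rates = np.repeat([base_rate, base_rate * rate_ratio], n_per_group)
    group = np.repeat(["A", "B"], n_per_group)
    t_event = rng.exponential(1.0 / rates)
    t_censor = rng.uniform(0.0, censor_horizon, size=2 * n_per_group)
    time = np.maximum(np.minimum(t_event, t_censor), 1e-6)
    event = (t_event <= t_censor).astype(int)
    ids = [f"T{j:04d}" for j in range(2 * n_per_group)]
    return CohortAnnotations(
        pd.DataFrame(
            {"group": group, "time": time, "event": event},
            index=pd.Index(ids, name="sample_id"),
        )
    )
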