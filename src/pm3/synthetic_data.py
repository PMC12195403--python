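"""Synthetic two-group expression cohorts with planted multiplicative shifts.

The generator emulates the statistical regime the screening method targets:
a modest cohort (12 cases vs 12 controls), a panel-scale set of genes
(~158), and subtle coordinated multiplicative group shifts (roughly -17%
to +30%) buried in biological noise.  Values are log-normal around each
gene's baseline with a mean-correcting offset, so the *arithmetic* group
mean equals the nominal baseline (controls) or the shifted baseline
(cases) exactly in expectation:

    control:  x ~ LogNormal(ln(mu) - sigma^2/2, sigma)
    case:     x ~ LogNormal(ln(mu (1 + delta)) - sigma^2/2, sigma)

With ``sigma = 0`` the draws are exactly the group means, so the percent
difference estimator recovers ``100 * delta`` without error — the limit
case several tests rely on.

An optional within-domain correlation adds a shared per-(sample, domain)
log-normal factor, splitting the log-variance into a shared and an
independent part while preserving the total — a crude stand-in for the
coordinated pathway-level regulation of real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression_io import ExpressionStudy
from .gene_model import GeneAnnotation, GeneModel

__all__ = [
    "SimGene",
    "SimSpec",
    "SimTruth",
    "simulate",
    "reference_spec",
    "REFERENCE_SHIFTS",
    "sim_gene_model",
    "spec_from_yaml",
    "spec_to_yaml",
]

#: Planted fractional shifts for the 26 bundled panel genes, anchored to
#: published ASD-cortex percent-difference estimates for these genes.
REFERENCE_SHIFTS: dict[str, float] = {
    "SUCLA2": -0.1193,
    "GOT1": -0.1182,
    "SLC25A11": -0.0799,
    "CKMT1A": -0.169,
    "GPT2": 0.0464,
    "GOT2": -0.0848,
    "GLS": -0.0808,
    "IDH3A": -0.0833,
    "MDH2": -0.0593,
    "IDH3B": -0.0813,
    "SHMT1": 0.0755,
    "MDH1": -0.1178,
    "OGDH": -0.0363,
    "PDHA1": -0.0225,
    "MAT2B": -0.119,
    "SFXN1": -0.0551,
    "MTHFD1": -0.0473,
    "DLD": -0.09,
    "SUOX": -0.066,
    "TST": 0.0036,
    "SUCLG2": 0.1383,
    "SLC5A6": -0.045,
    "SLC19A2": -0.035,
    "SLC19A3": 0.039,
    "PANK1": -0.118,
    "PANK2": 0.017,
}

#: Total panel size the generator fills up to with null genes.
PANEL_SIZE = 158


@dataclass(frozen=True)
class SimGene:
    """One simulated gene: baseline mean, planted shift and annotations."""

    symbol: str
    baseline: float  # mu_g, expression units (> 0)
    shift: float = 0.0  # delta_g, fraction; case mean = mu_g * (1 + delta_g)
    domain: str = "other"
    cofactors: tuple[str, ...] = ("none",)
    compartment: str = "unknown"

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"{self.symbol}: baseline must be > 0")
        if 1.0 + self.shift <= 0:
            raise ValueError(f"{self.symbol}: shift {self.shift} implies "
                             "a non-positive case mean")


@dataclass(frozen=True)
class SimSpec:
    """Cohort design: group sizes, gene list, noise level, seed."""

    genes: tuple[SimGene, ...]
    n_case: int = 12
    n_control: int = 12
    noise_sigma: float = 0.2  # log-scale s.d.
    domain_correlation: float = 0.0  # fraction of log-variance shared per domain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("group sizes must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.domain_correlation < 1.0:
            raise ValueError("domain_correlation must lie in [0, 1)")
        if not self.genes:
            raise ValueError("spec must contain at least one gene")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth per gene: planted shift and realized sample statistics."""

    table: pd.DataFrame  # index symbol; planted_shift, planted_pct_diff,
    # realized case/control means and pct_diff


def simulate(spec: SimSpec) -> tuple[ExpressionStudy, SimTruth]:
    """Draw one cohort from the spec (deterministic given the seed)."""
    rng = np.random.default_rng(spec.seed)
    n_genes = len(spec.genes)
    n_samples = spec.n_case + spec.n_control
    sigma = spec.noise_sigma

    mu = np.array([g.baseline for g in spec.genes])
    delta = np.array([g.shift for g in spec.genes])
    case_mean = mu * (1.0 + delta)

    # log-space location with mean correction: E[exp(N(m, s^2))] = exp(m + s^2/2)
    loc = np.log(np.column_stack([
        np.repeat(case_mean[:, None], spec.n_case, axis=1),
        np.repeat(mu[:, None], spec.n_control, axis=1),
    ])) - sigma**2 / 2.0

    if sigma == 0.0:
        values = np.exp(loc)
    else:
        rho = spec.domain_correlation
        s_shared = sigma * np.sqrt(rho)
        s_indep = sigma * np.sqrt(1.0 - rho)
        noise = s_indep * rng.standard_normal((n_genes, n_samples))
        if rho > 0.0:
            domains = [g.domain for g in spec.genes]
            for d in sorted(set(domains)):
                rows = [i for i, gd in enumerate(domains) if gd == d]
                shared = s_shared * rng.standard_normal(n_samples)
                noise[rows] += shared
        values = np.exp(loc + noise)

    sample_ids = [f"case_{i + 1:02d}" for i in range(spec.n_case)] + [
        f"ctrl_{i + 1:02d}" for i in range(spec.n_control)
    ]
    labels = {
        s: ("case" if s.startswith("case") else "control") for s in sample_ids
    }
    df = pd.DataFrame(values, index=[g.symbol for g in spec.genes], columns=sample_ids)
    df.index.name = "symbol"
    study = ExpressionStudy(df, labels)

    realized_case = df[[s for s in sample_ids if labels[s] == "case"]].mean(axis=1)
    realized_control = df[[s for s in sample_ids if labels[s] == "control"]].mean(axis=1)
    truth = pd.DataFrame(
        {
            "planted_shift": delta,
            "planted_pct_diff": 100.0 * delta,
            "realized_case_mean": realized_case.to_numpy(),
            "realized_control_mean": realized_control.to_numpy(),
            "realized_pct_diff": (
                100.0 * (realized_case / realized_control - 1.0)
            ).to_numpy(),
        },
        index=pd.Index([g.symbol for g in spec.genes], name="symbol"),
    )
    return study, SimTruth(table=truth)


def reference_spec(seed: int = 0) -> SimSpec:
    """The bundled panel-scale cohort design used throughout the tests.

    158 genes at 12 vs 12: the 26 annotated panel genes carry their
    published percent-difference estimates as planted shifts; the remaining
    132 filler genes (standing in for the rest of a full curated panel) are
    null.  Baselines are drawn log-uniformly over a realistic normalized-
    expression range (5-500 units) from the given seed.
    """
    from .gene_model import bundled_panel

    panel = bundled_panel()
    rng = np.random.default_rng(seed)
    n_null = PANEL_SIZE - len(panel)
    genes: list[SimGene] = []
    for ann in panel:
        genes.append(
            SimGene(
                symbol=ann.symbol,
                baseline=float(np.exp(rng.uniform(np.log(5.0), np.log(500.0)))),
                shift=REFERENCE_SHIFTS[ann.symbol],
                domain=ann.domain,
                cofactors=tuple(sorted(ann.cofactors)),
                compartment=ann.compartment,
            )
        )
    for i in range(n_null):
        genes.append(
            SimGene(
                symbol=f"NULL{i + 1:03d}",
                baseline=float(np.exp(rng.uniform(np.log(5.0), np.log(500.0)))),
                shift=0.0,
            )
        )
    return SimSpec(genes=tuple(genes), seed=seed)


def spec_to_yaml(spec: SimSpec, path) -> None:
    """Serialize a cohort design to YAML."""
    import yaml

    doc = {
        "n_case": spec.n_case,
        "n_control": spec.n_control,
        "noise_sigma": float(spec.noise_sigma),
        "domain_correlation": float(spec.domain_correlation),
        "seed": spec.seed,
        "genes": [
            {
                "symbol": g.symbol,
                "baseline": float(g.baseline),
                "shift": float(g.shift),
                "domain": g.domain,
                "cofactors": list(g.cofactors),
                "compartment": g.compartment,
            }
            for g in spec.genes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path, seed: int | None = None) -> SimSpec:
    """Load a cohort design from YAML; ``seed`` overrides the file's seed."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    genes = tuple(
        SimGene(
            symbol=g["symbol"],
            baseline=float(g["baseline"]),
            shift=float(g.get("shift", 0.0)),
            domain=g.get("domain", "other"),
            cofactors=tuple(g.get("cofactors", ["none"])),
            compartment=g.get("compartment", "unknown"),
        )
        for g in doc["genes"]
    )
    return SimSpec(
        genes=genes,
        n_case=int(doc.get("n_case", 12)),
        n_control=int(doc.get("n_control", 12)),
        noise_sigma=float(doc.get("noise_sigma", 0.2)),
        domain_correlation=float(doc.get("domain_correlation", 0.0)),
        seed=int(seed if seed is not None else doc.get("seed", 0)),
    )


def sim_gene_model(spec: SimSpec, name: str = "simulated_panel") -> GeneModel:
    """A gene model matching the simulated genes (for end-to-end runs)."""
    anns = tuple(
        GeneAnnotation(
            symbol=g.symbol,
            enzyme_name=f"simulated product of {g.symbol}",
            domain=g.domain,
            pathway="simulated",
            cofactors=frozenset(g.cofactors),
            compartment=g.compartment,
            functional_role="simulated",
        )
        for g in spec.genes
    )
    return GeneModel(anns, name=name, version="sim")
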