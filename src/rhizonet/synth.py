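"""Synthetic community, gene-count, and environmental data with planted structure.

Every downstream stage of the pipeline (prevalence filtering, RMT threshold
selection, network construction, module detection, enrichment testing) is
exercised against data whose ground truth is known because it was planted
here.  The community generator uses a latent-factor log-normal model: each
module m has one factor per replicate, f_mr ~ N(0,1); an OTU i belonging to
module m has log-abundance mu_i + lambda * f_mr + N(0, noise_sd); counts are
drawn multinomially at a fixed library size from the softmax of the
log-abundances (which mimics the compositional closure of sequencing), and
finally entries are zeroed independently with a dropout probability to mimic
detection limits.

The defaults emulate the study design the package targets: 12 biological
replicates per compartment, mixed bacterial/fungal module membership, and
correlated OTU blocks strong enough to survive correlation thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import AbundanceTable

ENV_VARIABLES = ("pH", "salinity", "ORP", "moisture", "TC", "TN", "NH4", "NO3", "NO2")


@dataclass
class SyntheticScenario:
    """Parameters of one compartment's synthetic community.

    ``modules`` lists planted correlated OTU blocks as ``(size, domain_mix)``
    pairs, where ``domain_mix`` is the fungal fraction of the block; OTUs not
    claimed by any module are independent background taxa whose replicate-to-
    replicate dynamics have scale ``background_sd`` on the log scale.  ``corr_strength``
    (lambda) scales the shared module factor; at lambda=0 all OTUs are
    independent.  ``domain_mix`` is the knob that makes a scenario
    "endosphere-like" (strong inter-domain mixing) versus "soil-like".
    """

    n_bacteria: int = 220
    n_fungi: int = 140
    n_replicates: int = 12
    modules: tuple[tuple[int, float], ...] = tuple((20, 0.4) for _ in range(6))
    corr_strength: float = 3.0
    noise_sd: float = 0.2
    baseline_log_sd: float = 1.0
    background_sd: float = 1.5
    dropout_prob: float = 0.0
    library_size: int = 50_000
    compartment: str = "Endo"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.corr_strength < 0:
            raise ValueError("corr_strength must be >= 0")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        total = sum(size for size, _ in self.modules)
        pool = self.n_bacteria + self.n_fungi
        if total > pool:
            raise ValueError(
                f"module sizes sum to {total} but only {pool} OTUs available "
                f"(modules: {self.modules})"
            )
        for i, (size, mix) in enumerate(self.modules, start=1):
            if size < 1:
                raise ValueError(f"module {i} has non-positive size {size}")
            if not 0 <= mix <= 1:
                raise ValueError(f"module {i} has domain_mix {mix} outside [0, 1]")

    @property
    def n_otus(self) -> int:
        return self.n_bacteria + self.n_fungi


@dataclass
class GeneScenario:
    """Parameters of a synthetic gene-count table (gene x compartment).

    ``genes`` are ``(name, length_bp, baseline_rate)`` triples; counts per
    compartment are Poisson with mean proportional to ``depth * rate *
    length``, so longer genes accumulate more reads at equal molar abundance.
    ``enriched`` plants fold changes: ``gene -> (compartment, fold)`` boosts
    that gene's rate in one compartment.
    """

    genes: tuple[tuple[str, int, float], ...]
    enriched: dict = field(default_factory=dict)
    depth: int = 100_000
    compartments: tuple[str, ...] = ("Non", "Rhi", "Epi", "Endo")
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g[0] for g in self.genes]
        if len(names) != len(set(names)):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene names: {dups}")
        for name, length, rate in self.genes:
            if length <= 0:
                raise ValueError(f"gene {name!r} has non-positive length {length}")
            if rate < 0:
                raise ValueError(f"gene {name!r} has negative baseline rate")
        for gene, (comp, fold) in self.enriched.items():
            if gene not in names:
                raise ValueError(f"enriched gene {gene!r} not in scenario")
            if comp not in self.compartments:
                raise ValueError(f"unknown compartment {comp!r} for gene {gene!r}")
            if fold <= 1:
                raise ValueError(f"fold_change for {gene!r} must be > 1, got {fold}")


def _module_assignment(scenario: SyntheticScenario, rng: np.random.Generator):
    """Assign OTUs to modules and domains.

    Returns (module_label per OTU, domain per OTU, otu ids).  Module labels
    are 1-based; background OTUs get label 0.  Within each module the fungal
    fraction approximates the module's domain_mix.
    """
    n = scenario.n_otus
    module = np.zeros(n, dtype=int)
    domain = np.empty(n, dtype=object)
    b_left, f_left = scenario.n_bacteria, scenario.n_fungi
    pos = 0
    for m, (size, mix) in enumerate(scenario.modules, start=1):
        n_fungal = min(int(round(size * mix)), f_left)
        n_bact = size - n_fungal
        if n_bact > b_left:  # domain pool exhausted; rebalance
            n_fungal += n_bact - b_left
            n_bact = b_left
        module[pos : pos + size] = m
        domain[pos : pos + n_bact] = "bacteria"
        domain[pos + n_bact : pos + size] = "fungi"
        b_left -= n_bact
        f_left -= n_fungal
        pos += size
    domain[pos : pos + b_left] = "bacteria"
    domain[pos + b_left :] = "fungi"
    otu_ids = []
    counters = {"bacteria": 0, "fungi": 0}
    for d in domain:
        counters[d] += 1
        prefix = "OTUB" if d == "bacteria" else "OTUF"
        otu_ids.append(f"{prefix}_{counters[d]:04d}")
    return module, domain, otu_ids


def generate_community(scenario: SyntheticScenario):
    """Generate a compartment's abundance table with planted module structure.

    Returns ``(table, planted_modules)`` where ``planted_modules`` maps OTU id
    to its planted module label (0 = background).  The same seed always yields
    a bitwise-identical table; the random draws occur in a fixed order
    (factors first, then baselines, OTU noise, counts, dropout).
    """
    rng = np.random.default_rng(scenario.seed)
    n, r = scenario.n_otus, scenario.n_replicates
    n_modules = len(scenario.modules)
    # Factor draw comes first so generate_env_matrix can reproduce the
    # community gradient (the first module's factor) from the same seed.
    factors = rng.standard_normal((max(n_modules, 1), r))
    module, domain, otu_ids = _module_assignment(scenario, rng)
    mu = rng.normal(0.0, scenario.baseline_log_sd, size=n)

    log_abund = mu[:, None] + rng.normal(0.0, scenario.noise_sd, size=(n, r))
    in_module = module > 0
    log_abund[in_module] += scenario.corr_strength * factors[module[in_module] - 1]
    # Background taxa fluctuate independently on a lognormal scale of their
    # own; without this, their near-constant abundances would all mirror the
    # compositional denominator and correlate spuriously.
    n_bg = int((~in_module).sum())
    if n_bg and scenario.background_sd > 0:
        log_abund[~in_module] += rng.normal(0.0, scenario.background_sd, size=(n_bg, r))

    # Multinomial on the per-sample softmax keeps the data compositional, as
    # in relative-abundance sequencing: column sums equal library_size.
    counts = np.empty((n, r), dtype=np.int64)
    for j in range(r):
        shifted = log_abund[:, j] - log_abund[:, j].max()
        p = np.exp(shifted)
        p /= p.sum()
        counts[:, j] = rng.multinomial(scenario.library_size, p)

    if scenario.dropout_prob > 0:
        drop = rng.random((n, r)) < scenario.dropout_prob
        counts[drop] = 0

    samples = [f"{scenario.compartment}_{j + 1:02d}" for j in range(r)]
    table = AbundanceTable(
        values=pd.DataFrame(counts, index=otu_ids, columns=samples),
        domain=pd.Series(domain, index=otu_ids),
        compartment=pd.Series(scenario.compartment, index=samples),
        replicate=pd.Series(np.arange(1, r + 1), index=samples),
    )
    planted = pd.Series(module, index=otu_ids, name="module")
    return table, planted


def generate_gene_counts(scenario: GeneScenario) -> pd.DataFrame:
    """Generate a gene x compartment read-count table with planted enrichment.

    Returns a DataFrame indexed by gene name with a ``length_bp`` column and
    one integer count column per compartment.  Counts are Poisson with mean
    ``depth * rate * length / sum(rate * length)``; a planted fold change
    multiplies the rate in its target compartment only, so the expected count
    ratio between the target and any other compartment is the fold change.
    """
    rng = np.random.default_rng(scenario.seed)
    names = [g[0] for g in scenario.genes]
    lengths = np.array([g[1] for g in scenario.genes], dtype=float)
    rates = np.array([g[2] for g in scenario.genes], dtype=float)

    counts = {}
    baseline_total = (rates * lengths).sum()
    for comp in scenario.compartments:
        comp_rates = rates.copy()
        for gene, (target, fold) in scenario.enriched.items():
            if target == comp:
                comp_rates[names.index(gene)] *= fold
        weight = comp_rates * lengths
        # normalize by the *baseline* weight total so a planted fold change
        # is exactly the expected count ratio between compartments
        mean = scenario.depth * weight / baseline_total if baseline_total > 0 else np.zeros_like(weight)
        counts[comp] = rng.poisson(mean) if scenario.depth > 0 else np.zeros(len(names), dtype=int)

    out = pd.DataFrame(counts, index=pd.Index(names, name="gene"))
    out.insert(0, "length_bp", lengths.astype(int))
    return out


def generate_env_matrix(
    n_samples: int,
    gradient_corr: float,
    seed: int,
    variables: tuple[str, ...] = ENV_VARIABLES,
) -> pd.DataFrame:
    """Generate a samples x variables environmental table.

    The first variable tracks the community gradient — the first module
    factor drawn by :func:`generate_community` under the same seed — with
    correlation ``gradient_corr``; the remaining variables are independent
    standard normals.  At ``gradient_corr=1`` the first variable *is* the
    gradient (noise-free).
    """
    if not -1 <= gradient_corr <= 1:
        raise ValueError(f"gradient_corr must be in [-1, 1], got {gradient_corr}")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    gradient = rng.standard_normal(n_samples)  # matches generate_community's first draw
    env = rng.standard_normal((n_samples, len(variables)))
    g = gradient_corr
    env[:, 0] = g * gradient + np.sqrt(1 - g * g) * env[:, 0]
    samples = [f"S{j + 1:02d}" for j in range(n_samples)]
    return pd.DataFrame(env, index=samples, columns=list(variables))
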