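"""TPM profiles and compartment enrichment of functional gene panels.

Two gene panels matter for microbial cell-cell interaction across the
soil-root interface: quorum-sensing circuits (module 1: cqsA, tdh, luxR;
module 2: lasI, rhlI, pqsH, lasR) and cobamide (vitamin-B12 family)
biosynthesis, whose corrin-ring adenosylation splits into an aerobic route
(cobG, cobF, cobA) and an anaerobic one (cbiT, cbiE).  Panel membership is
read from an editable data file so genes can be added without code changes.

Read counts are displayed as transcripts per million (TPM): counts are
divided by gene length and rescaled so each sample sums to 1e6.  Enrichment
between compartments is tested on the raw read counts with a two-sided
Fisher's exact test per gene (gene reads versus all other reads), corrected
across genes within each compartment pair by Benjamini-Hochberg; q < 0.05
flags significance.  TPM is for display only — the exact test needs counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GenePanel:
    """Named gene set; every member carries a subgroup tag."""

    name: str
    members: dict  # gene -> subgroup tag

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"panel {self.name!r} has no members")

    @property
    def genes(self) -> list[str]:
        return list(self.members)


def load_panels(path=None) -> dict:
    """Load panel definitions (panel, gene, subgroup TSV); default ships with the package."""
    if path is None:
        path = resources.files("rhizonet.data") / "gene_panels.tsv"
    df = pd.read_csv(path, sep="\t")
    panels = {}
    for name, grp in df.groupby("panel"):
        if grp["gene"].duplicated().any():
            dups = grp.loc[grp["gene"].duplicated(), "gene"].tolist()
            raise ValueError(f"duplicate genes in panel {name!r}: {dups}")
        panels[name] = GenePanel(name=name, members=dict(zip(grp["gene"], grp["subgroup"])))
    return panels


def tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: (c_g / L_g) / sum_h (c_h / L_h) * 1e6 per sample."""
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"genes without length: {missing}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom.index[denom == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample columns: {zero}")
    return rate.div(denom, axis=1) * 1e6


def panel_profile(tpm: pd.DataFrame, panel: GenePanel, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Panel-restricted TPM matrix with an ``undetected`` companion flag.

    A gene is undetected in a sample when its raw count is zero — distinct
    from a merely low TPM.  Panel genes absent from the table appear as
    all-NaN rows flagged undetected everywhere, never as an error.  Returns
    a long-format frame (gene, subgroup, sample, tpm, undetected).
    """
    rows = []
    for gene in panel.genes:
        for sample in tpm.columns:
            present = gene in tpm.index
            value = float(tpm.loc[gene, sample]) if present else np.nan
            if counts is not None and present:
                undetected = bool(counts.loc[gene, sample] == 0)
            else:
                undetected = (not present) or value == 0
            rows.append((gene, panel.members[gene], sample, value, undetected))
    return pd.DataFrame(rows, columns=["gene", "subgroup", "sample", "tpm", "undetected"])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def pairwise_enrichment(
    counts: pd.DataFrame,
    totals: pd.Series,
    panel: GenePanel | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher/BH enrichment of each gene between every compartment pair.

    ``counts`` is gene x compartment; ``totals`` gives the read total per
    compartment used as the denominator (all annotated reads).  For gene g
    and compartments (A, B) the 2x2 table is
    ``[[c_gA, T_A - c_gA], [c_gB, T_B - c_gB]]``; BH correction is applied
    across genes within each compartment pair.
    """
    totals = totals.reindex(counts.columns)
    if (counts.gt(totals, axis=1)).any().any():
        raise ValueError("gene count exceeds compartment total")
    genes = [g for g in (panel.genes if panel else counts.index) if g in counts.index]
    rows = []
    for comp_a, comp_b in combinations(counts.columns, 2):
        t_a, t_b = int(totals[comp_a]), int(totals[comp_b])
        pvals = []
        for gene in genes:
            c_a, c_b = int(counts.loc[gene, comp_a]), int(counts.loc[gene, comp_b])
            table = [[c_a, t_a - c_a], [c_b, t_b - c_b]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            pvals.append(p)
            rows.append([gene, comp_a, comp_b, c_a, c_b, t_a, t_b, float(odds), float(p)])
        qvals = bh_adjust(pvals)
        for offset, q in enumerate(qvals):
            rows[len(rows) - len(qvals) + offset].append(float(q))
    out = pd.DataFrame(
        rows,
        columns=["gene", "comp_a", "comp_b", "count_a", "count_b", "total_a", "total_b", "odds_ratio", "p", "q"],
    )
    out["significant"] = out["q"] < alpha
    return out


def detection_frequency(
    gene_taxonomy: pd.DataFrame, panel: GenePanel, top_k: int = 10
) -> pd.DataFrame:
    """Family x compartment detection frequencies for a panel's gene records.

    ``gene_taxonomy`` has one row per annotated read/gene record with
    columns ``gene``, ``family``, ``compartment``.  Frequencies are the
    fraction of the compartment's panel records assigned to each family;
    families outside the overall top ``top_k`` are pooled into ``other``,
    and records without a family assignment leave the column summing below 1.
    """
    if gene_taxonomy.empty:
        raise ValueError("empty gene-taxonomy table")
    records = gene_taxonomy[gene_taxonomy["gene"].isin(panel.genes)].copy()
    if records.empty:
        raise ValueError(f"no records for panel {panel.name!r}")
    assigned = records.dropna(subset=["family"])
    overall = assigned["family"].value_counts()
    top = list(overall.index[:top_k])
    assigned = assigned.assign(
        family=assigned["family"].where(assigned["family"].isin(top), "other")
    )
    denom = records.groupby("compartment").size()
    freq = (
        assigned.groupby(["family", "compartment"]).size().unstack(fill_value=0).div(denom, axis=1)
    ).fillna(0.0)
    order = [f for f in top if f in freq.index] + (["other"] if "other" in freq.index else [])
    return freq.loc[order]
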