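"""OTU abundance tables and the filtering steps that precede network construction.

The central container is :class:`AbundanceTable`: an OTU x sample matrix of
counts (or relative abundances) with a per-OTU domain label (bacteria/fungi)
and per-sample compartment/replicate metadata.  Co-occurrence networks are
built per compartment from 12 biological replicates; before correlation, OTUs
are screened by a prevalence rule (detected in at least 8 of the 12
replicates) and optionally by a minimum share of total abundance, then
converted to per-sample relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DOMAINS = ("bacteria", "fungi")
COMPARTMENTS = ("Non", "Rhi", "Epi", "Endo")


@dataclass
class AbundanceTable:
    """OTU x sample abundance matrix with domain and sample metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by OTU id, columns by sample id.  Nonnegative.
    domain : pandas.Series
        Per-OTU label, ``"bacteria"`` or ``"fungi"``, indexed like the rows.
    compartment : pandas.Series
        Per-sample compartment label in ``{Non, Rhi, Epi, Endo}``.
    replicate : pandas.Series
        Per-sample integer replicate number.
    mode : str
        ``"counts"`` or ``"relative"``.  In relative mode every column sums
        to 1 (to 1e-9).
    """

    values: pd.DataFrame
    domain: pd.Series
    compartment: pd.Series
    replicate: pd.Series
    mode: str = "counts"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if (v.to_numpy() < 0).any():
            bad = v.index[(v < 0).any(axis=1)].tolist()
            raise ValueError(f"negative abundance values in OTUs: {bad}")
        for name, meta in (("domain", self.domain),):
            unknown = set(meta) - set(DOMAINS)
            if unknown:
                raise ValueError(f"unknown {name} labels: {sorted(unknown)}")
        if not self.domain.index.equals(v.index):
            self.domain = self.domain.reindex(v.index)
            if self.domain.isna().any():
                missing = self.domain.index[self.domain.isna()].tolist()
                raise ValueError(f"OTUs without domain label: {missing}")
        for name, meta in (("compartment", self.compartment), ("replicate", self.replicate)):
            if not meta.index.equals(v.columns):
                meta = meta.reindex(v.columns)
                if meta.isna().any():
                    missing = meta.index[meta.isna()].tolist()
                    raise ValueError(f"samples without {name}: {missing}")
                setattr(self, name, meta)
        unknown_comp = set(self.compartment) - set(COMPARTMENTS)
        if unknown_comp:
            raise ValueError(f"unknown compartment labels: {sorted(unknown_comp)}")
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = v.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("relative-abundance columns must sum to 1")

    # -- convenience -------------------------------------------------------
    @property
    def n_otus(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def otu_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    def select_compartment(self, compartment: str) -> "AbundanceTable":
        """Restrict the table to the samples of one compartment."""
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        cols = self.compartment.index[self.compartment == compartment]
        return replace(
            self,
            values=self.values[cols],
            compartment=self.compartment[cols],
            replicate=self.replicate[cols],
        )

    def select_domain(self, domain: str) -> "AbundanceTable":
        """Restrict the table to OTUs of one domain."""
        rows = self.domain.index[self.domain == domain]
        return replace(self, values=self.values.loc[rows], domain=self.domain[rows])


def read_abundance(path, metadata_path, domain_label: str | None = None) -> AbundanceTable:
    """Read a tab-separated OTU table plus sample metadata.

    The abundance file has OTU ids in the first column and one column per
    sample.  The metadata file has columns ``sample_id``, ``compartment``,
    ``replicate`` and must cover every sample column.  ``domain_label``
    assigns one domain to every OTU in the file; alternatively the abundance
    file may carry a ``domain`` column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    meta = pd.read_csv(metadata_path, sep="\t")
    required = {"sample_id", "compartment", "replicate"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")

    if "domain" in raw.columns:
        domain = raw["domain"].astype(str)
        raw = raw.drop(columns="domain")
    elif domain_label is not None:
        domain = pd.Series(domain_label, index=raw.index)
    else:
        raise ValueError("provide domain_label or a 'domain' column in the table")

    unknown = [s for s in raw.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"sample columns absent from metadata: {unknown}")

    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        rows = [
            f"line {i + 2}: OTU {otu!r}"  # +2: header line plus 1-based numbering
            for i, otu in enumerate(values.index)
            if values.loc[otu].isna().any()
        ]
        raise ValueError("non-numeric abundance values at " + "; ".join(rows))
    neg = values.lt(0).any(axis=1)
    if neg.any():
        rows = [f"line {i + 2}: OTU {otu!r}" for i, otu in enumerate(values.index) if neg[otu]]
        raise ValueError("negative abundance values at " + "; ".join(rows))

    return AbundanceTable(
        values=values,
        domain=domain,
        compartment=meta.loc[values.columns, "compartment"],
        replicate=meta.loc[values.columns, "replicate"].astype(int),
    )


def write_abundance(table: AbundanceTable, path, metadata_path=None, header_comment: str | None = None) -> None:
    """Write a table (and optionally its sample metadata) as tab-separated files."""
    out = table.values.copy()
    out.insert(0, "domain", table.domain)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, sep="\t", index_label="otu_id")
    if metadata_path is not None:
        meta = pd.DataFrame(
            {"compartment": table.compartment, "replicate": table.replicate}
        )
        meta.to_csv(metadata_path, sep="\t", index_label="sample_id")


def prevalence_filter(table: AbundanceTable, min_detected: int = 8, of_replicates: int = 12) -> AbundanceTable:
    """Keep OTUs detected (strictly positive) in at least ``min_detected`` samples.

    The rule is applied within a single compartment of ``of_replicates``
    replicate samples; detection means any nonzero abundance, with no
    minimum-count threshold.  Row order is preserved and the operation is
    idempotent.
    """
    if table.n_samples != of_replicates:
        raise ValueError(
            f"prevalence filter expects {of_replicates} replicate samples, got {table.n_samples}"
        )
    detected = (table.values > 0).sum(axis=1)
    keep = detected.index[detected >= min_detected]
    return replace(table, values=table.values.loc[keep], domain=table.domain[keep])


def abundance_cut(table: AbundanceTable, min_fraction: float = 1e-4) -> AbundanceTable:
    """Drop OTUs whose share of the table's total abundance is below ``min_fraction``.

    Default 1e-4 keeps OTUs above 0.01% of total abundance.
    """
    totals = table.values.sum(axis=1)
    share = totals / totals.sum()
    keep = share.index[share > min_fraction]
    return replace(table, values=table.values.loc[keep], domain=table.domain[keep])


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to per-sample relative abundances (columns sum to 1)."""
    sums = table.values.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample columns: {zero}")
    return replace(table, values=table.values / sums, mode="relative")


def merge_domains(bact: AbundanceTable, fungi: AbundanceTable) -> AbundanceTable:
    """Row-concatenate a bacterial and a fungal table over identical samples.

    The result feeds the bacterial-fungal association (BFA) network; OTU id
    namespaces must not collide (the OTUB_/OTUF_ prefixes keep them apart).
    """
    if bact.sample_ids != fungi.sample_ids:
        diff = sorted(set(bact.sample_ids) ^ set(fungi.sample_ids))
        raise ValueError(f"sample sets differ between domains: {diff or 'ordering mismatch'}")
    collisions = set(bact.otu_ids) & set(fungi.otu_ids)
    if collisions:
        raise ValueError(f"OTU ids collide across domains: {sorted(collisions)}")
    if bact.mode != fungi.mode:
        raise ValueError("cannot merge tables in different modes")
    merged_values = pd.concat([bact.values, fungi.values], axis=0)
    if bact.mode == "relative":
        # Concatenating two relative tables doubles the column sums; renormalize.
        merged_values = merged_values / merged_values.sum(axis=0)
    return AbundanceTable(
        values=merged_values,
        domain=pd.concat([bact.domain, fungi.domain]),
        compartment=bact.compartment,
        replicate=bact.replicate,
        mode=bact.mode,
    )
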