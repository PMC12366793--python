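"""PAO sub-community identification from OTU tables.

Implements the preprocessing chain applied to FACS-sorted 16S libraries:
abundance/quality/taxonomy filtering, the four-gene (ppk1, ppx, phaZ, phaC)
polyP+PHA capability requirement, FACS enrichment-efficiency ratios, and the
seeded replicate pooling used ahead of single-cell work.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "OtuTable",
    "FunctionTable",
    "PAO_GENES",
    "filter_otus",
    "require_pao_genes",
    "enrichment_efficiency",
    "pool_replicates",
]

PAO_GENES = ("ppk1", "ppx", "phaZ", "phaC")

_GENUS_RE = re.compile(r"g__([^;]*)")


@dataclass
class OtuTable:
    """Taxa x samples count table with taxonomy and per-OTU quality scores.

    counts : DataFrame, taxa (index) x samples (columns), nonnegative ints
    taxonomy : per-taxon lineage string with a ``g__Genus`` slot
    e_score : per-taxon opaque quality number from the sequencing pipeline
    pao_candidate : per-taxon flag (ground-truth marker in synthetic tables)
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    e_score: pd.Series
    pao_candidate: pd.Series | None = None

    def __post_init__(self):
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        self.e_score = self.e_score.reindex(self.counts.index)
        if self.pao_candidate is not None:
            self.pao_candidate = (
                self.pao_candidate.reindex(self.counts.index).fillna(False).astype(bool)
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (columns sum to 1).

        All-zero samples are excluded from the result with a warning.
        """
        totals = self.counts.sum(axis=0)
        zero = totals == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} all-zero sample(s) excluded from "
                "relative-abundance computation"
            )
        cols = totals.index[~zero]
        return self.counts[cols] / totals[cols]

    def genus(self) -> pd.Series:
        """Extract the genus slot from each lineage ('' when absent)."""

        def _one(lineage) -> str:
            if not isinstance(lineage, str):
                return ""
            m = _GENUS_RE.search(lineage)
            g = m.group(1).strip() if m else ""
            if g.lower() in {"", "unclassified", "uncultured", "na"}:
                return ""
            return g

        return self.taxonomy.map(_one)

    def subset(self, taxa) -> "OtuTable":
        taxa = pd.Index(taxa)
        return OtuTable(
            counts=self.counts.loc[taxa],
            taxonomy=self.taxonomy.loc[taxa],
            e_score=self.e_score.loc[taxa],
            pao_candidate=None
            if self.pao_candidate is None
            else self.pao_candidate.loc[taxa],
        )

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.insert(0, "taxonomy", self.taxonomy)
        df.insert(1, "e_score", self.e_score)
        if self.pao_candidate is not None:
            df.insert(2, "pao_candidate", self.pao_candidate.astype(int))
        df.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col="otu_id")
        meta_cols = [c for c in ("taxonomy", "e_score", "pao_candidate") if c in df]
        counts = df.drop(columns=meta_cols)
        return cls(
            counts=counts.astype(int),
            taxonomy=df["taxonomy"] if "taxonomy" in df else pd.Series("", index=df.index),
            e_score=df["e_score"] if "e_score" in df else pd.Series(np.nan, index=df.index),
            pao_candidate=df["pao_candidate"].astype(bool)
            if "pao_candidate" in df
            else None,
        )


@dataclass
class FunctionTable:
    """Per-taxon gene presence and per-category functional contributions.

    genes : DataFrame, taxa x {ppk1, ppx, phaZ, phaC}, boolean
    contributions : DataFrame, taxa x function categories, nonnegative f_i
    """

    genes: pd.DataFrame
    contributions: pd.DataFrame = field(default=None)

    def __post_init__(self):
        missing = [g for g in PAO_GENES if g not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table lacks columns: {missing}")
        self.genes = self.genes.astype(bool)
        if self.contributions is not None and (
            self.contributions.to_numpy() < 0
        ).any():
            raise ValueError("functional contributions must be nonnegative")

    def to_tsv(self, path) -> None:
        df = self.genes.astype(int)
        if self.contributions is not None:
            df = df.join(self.contributions)
        df.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path) -> "FunctionTable":
        df = pd.read_csv(path, sep="\t", index_col="otu_id")
        genes = df[list(PAO_GENES)].astype(bool)
        contrib = df.drop(columns=list(PAO_GENES))
        return cls(genes=genes, contributions=contrib if len(contrib.columns) else None)


def filter_otus(
    table: OtuTable,
    min_rel_abund: float = 1e-4,
    min_escore: float = 99.0,
) -> tuple[OtuTable, dict[str, str]]:
    """Apply the OTU retention rules and return (filtered table, removal ledger).

    A taxon is kept when its overall relative abundance (mean of per-sample
    relative abundances) is >= ``min_rel_abund`` (default 0.01%), its e-score
    is >= ``min_escore`` (default 99), and its lineage carries a genus. The
    ledger maps each removed taxon to its first failing rule in the fixed
    order abundance -> escore -> genus, so reports are reproducible.
    """
    if len(table.taxa) == 0:
        warnings.warn("empty OTU table: nothing to filter")
        return table, {}
    rel = table.relative_abundance()
    overall = rel.mean(axis=1)
    genus = table.genus()
    ledger: dict[str, str] = {}
    keep = []
    for taxon in table.taxa:
        if overall.get(taxon, 0.0) < min_rel_abund:
            ledger[taxon] = "abundance"
        elif not (pd.notna(table.e_score[taxon]) and table.e_score[taxon] >= min_escore):
            ledger[taxon] = "escore"
        elif genus[taxon] == "":
            ledger[taxon] = "genus"
        else:
            keep.append(taxon)
    return table.subset(keep), ledger


def require_pao_genes(table: OtuTable, fn: FunctionTable) -> OtuTable:
    """Keep only taxa carrying all four polyP/PHA cycling genes.

    ppk1/ppx cover polyphosphate synthesis/degradation and phaC/phaZ cover
    PHA synthesis/degradation; a PAO as defined here needs the full set.
    """
    missing = table.taxa.difference(fn.genes.index)
    if len(missing):
        raise KeyError(
            f"taxa absent from function table: {list(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    has_all = fn.genes.loc[table.taxa, list(PAO_GENES)].all(axis=1)
    return table.subset(table.taxa[has_all.to_numpy()])


def enrichment_efficiency(
    sorted_table: OtuTable, bulk_table: OtuTable
) -> pd.DataFrame:
    """Per-taxon FACS enrichment ratio: rel. abundance sorted / bulk.

    Taxa present in the sorted library but absent from bulk get an infinite
    ratio and ``absent_in_bulk=True``. Ratios are computed on overall (mean
    per-sample) relative abundances.
    """
    shared = sorted_table.taxa.intersection(bulk_table.taxa)
    if len(shared) == 0:
        raise ValueError("no shared taxa between sorted and bulk tables")
    rs = sorted_table.relative_abundance().mean(axis=1)
    rb = bulk_table.relative_abundance().mean(axis=1)
    out = pd.DataFrame(index=sorted_table.taxa)
    bulk_vals = rb.reindex(sorted_table.taxa).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = rs.reindex(sorted_table.taxa) / bulk_vals
    out["ratio"] = ratio.replace(np.nan, np.inf)
    out["absent_in_bulk"] = bulk_vals == 0.0
    return out


def pool_replicates(
    table: OtuTable,
    design: pd.DataFrame,
    k_pools: int = 3,
    seed: int = 0,
) -> tuple[OtuTable, pd.DataFrame]:
    """Randomly pool replicates within each treatment and sum their counts.

    Mirrors the 6 -> 3 replicate pooling used to feed FACS/SCRS: within every
    treatment the replicates are partitioned (seeded, uniformly at random)
    into ``k_pools`` equal groups whose counts are added. Returns the pooled
    table and a pooled design with columns sample_id, treatment, warming,
    clipping, pool.
    """
    rng = substream(seed, "pool_replicates")
    design = design.set_index("sample_id", drop=False)
    pooled_cols = {}
    rows = []
    for treat, grp in design.groupby("treatment", sort=True):
        ids = list(grp["sample_id"])
        if len(ids) % k_pools != 0:
            raise ValueError(
                f"treatment {treat}: {len(ids)} replicates not divisible "
                f"into {k_pools} pools"
            )
        size = len(ids) // k_pools
        perm = rng.permutation(len(ids))
        for p in range(k_pools):
            members = [ids[i] for i in perm[p * size : (p + 1) * size]]
            name = f"{treat}_pool{p + 1}"
            pooled_cols[name] = table.counts[members].sum(axis=1)
            rows.append(
                {
                    "sample_id": name,
                    "treatment": treat,
                    "warming": int(grp["warming"].iloc[0]),
                    "clipping": int(grp["clipping"].iloc[0]),
                    "block": p + 1,
                    "replicate": p + 1,
                    "pool": p + 1,
                    "members": ",".join(members),
                }
            )
    pooled_counts = pd.DataFrame(pooled_cols, index=table.taxa)
    pooled = OtuTable(
        counts=pooled_counts,
        taxonomy=table.taxonomy,
        e_score=table.e_score,
        pao_candidate=table.pao_candidate,
    )
    return pooled, pd.DataFrame(rows)
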