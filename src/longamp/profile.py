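"""Community profiling: exact-dereplication ASV calling, LCA taxonomic
classification against a reference amplicon set, classification-depth rates,
taxon aggregation, and rarefaction.

Denoising note: reads handled here are assumed error-free or near
error-free (the simulator's default), so ASV calling is exact sequence
dereplication with an optional minimum-total-count filter. This is the
pipeline's deliberate stand-in for abundance-aware denoisers (DADA2-style
error models are out of scope); it preserves the downstream analysis logic
exactly on clean reads.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species", "strain",
)
_RANK_DEPTH = {r: i + 1 for i, r in enumerate(RANKS)}


class FeatureTable:
    """Samples × features count matrix with feature sequences attached.

    ``counts`` is held features-as-rows, samples-as-columns (the common
    amplicon-pipeline layout). All-zero feature rows are dropped at
    construction; counts must be non-negative integers; when sequences are
    given, every feature id must have one (taxon-aggregated tables carry no
    sequences).
    """

    def __init__(self, counts: pd.DataFrame, sequences: Mapping[str, str] | None = None):
        counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        keep = counts.sum(axis=1) > 0
        counts = counts.loc[keep]
        if sequences is not None:
            missing = set(counts.index) - sequences.keys()
            if missing:
                raise ValueError(f"features without sequences: {sorted(missing)[:5]}")
            sequences = {f: sequences[f] for f in counts.index}
        self.counts = counts
        self.sequences = sequences

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __repr__(self) -> str:
        return (f"FeatureTable({self.counts.shape[0]} features x "
                f"{self.counts.shape[1]} samples)")


@dataclass(frozen=True)
class TaxonomyAssignment:
    feature_id: str
    lineage: tuple[str, ...]
    deepest_rank: str  # a rank name or "unclassified"


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference amplicon with its full ranked lineage."""

    id: str
    lineage: tuple[str, ...]
    sequence: str

    def __post_init__(self):
        if not (1 <= len(self.lineage) <= len(RANKS)):
            raise ValueError(f"reference {self.id}: lineage must have 1..{len(RANKS)} ranks")
        if any(not r for r in self.lineage):
            raise ValueError(f"reference {self.id}: empty rank label (lineage gap)")


def dereplicate_asvs(
    reads_per_sample: Mapping[str, Sequence[str]],
    min_total_count: int = 1,
) -> FeatureTable:
    """Exact dereplication: each distinct read sequence becomes a feature.

    Features are ordered by descending total count (sequence as tie-break)
    and named ASV_0001, ASV_0002, ... Features whose total count across
    samples falls below ``min_total_count`` are removed.
    """
    counters = {s: Counter(reads) for s, reads in reads_per_sample.items()}
    total: Counter = Counter()
    for c in counters.values():
        total.update(c)
    ordered = sorted(total, key=lambda seq: (-total[seq], seq))
    ordered = [seq for seq in ordered if total[seq] >= min_total_count]
    ids = [f"ASV_{i + 1:04d}" for i in range(len(ordered))]
    data = {
        sample: [counters[sample].get(seq, 0) for seq in ordered]
        for sample in reads_per_sample
    }
    counts = pd.DataFrame(data, index=ids)
    return FeatureTable(counts, dict(zip(ids, ordered)))


def _hamming(a: str, b: str) -> int:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return int(np.count_nonzero(xa != xb))


def _distance(query: str, ref: str, max_distance: int) -> int | None:
    """Substitution-only Hamming for equal lengths; banded edit distance for
    length differences up to 10; no match beyond that."""
    dlen = abs(len(query) - len(ref))
    if dlen == 0:
        d = _hamming(query, ref)
    elif dlen <= 10:
        res = edlib.align(query, ref, mode="NW", task="distance", k=max_distance)
        d = res["editDistance"]
        if d == -1:
            return None
    else:
        return None
    return d if d <= max_distance else None


def classify_lca(
    sequence: str,
    reference: Sequence[ReferenceRecord],
    max_distance: int | None = None,
    feature_id: str = "feature",
) -> TaxonomyAssignment:
    """Classify one sequence as the lowest common ancestor of its best
    reference matches.

    All references at the best (smallest) distance within ``max_distance``
    (default 1% of the query length) vote; the assignment is the longest
    shared lineage prefix. No reference within range → "unclassified".
    """
    if max_distance is None:
        max_distance = max(1, round(0.01 * len(sequence)))
    best_d: int | None = None
    best: list[ReferenceRecord] = []
    for ref in reference:
        d = _distance(sequence, ref.sequence, max_distance)
        if d is None:
            continue
        if best_d is None or d < best_d:
            best_d, best = d, [ref]
        elif d == best_d:
            best.append(ref)
    if not best:
        return TaxonomyAssignment(feature_id, (), "unclassified")
    lineage = list(best[0].lineage)
    for ref in best[1:]:
        k = 0
        while k < len(lineage) and k < len(ref.lineage) and lineage[k] == ref.lineage[k]:
            k += 1
        lineage = lineage[:k]
    if not lineage:
        return TaxonomyAssignment(feature_id, (), "unclassified")
    return TaxonomyAssignment(feature_id, tuple(lineage), RANKS[len(lineage) - 1])


def classify_table(
    table: FeatureTable,
    reference: Sequence[ReferenceRecord],
    max_distance: int | None = None,
) -> dict[str, TaxonomyAssignment]:
    if table.sequences is None:
        raise ValueError("table carries no feature sequences")
    return {
        fid: classify_lca(table.sequences[fid], reference, max_distance, fid)
        for fid in table.feature_ids
    }


def classification_rate(
    table: FeatureTable,
    assignments: Mapping[str, TaxonomyAssignment],
    rank: str,
) -> pd.Series:
    """Per-sample proportion of reads whose feature is classified at ``rank``
    or deeper. Median across samples is the headline summary
    (``classification_rate(...).median()``)."""
    if rank not in _RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    need = _RANK_DEPTH[rank]
    ok = [fid for fid in table.feature_ids
          if len(assignments[fid].lineage) >= need]
    totals = table.sample_totals()
    classified = table.counts.loc[ok].sum(axis=0)
    return (classified / totals).rename(f"classified_at_{rank}")


def rarefy(table: FeatureTable, depth: int, seed: int | None = None) -> FeatureTable:
    """Subsample each sample to exactly ``depth`` reads without replacement
    (multivariate hypergeometric). Samples with fewer than ``depth`` total
    reads are dropped with a warning. Deterministic given ``seed``."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    cols = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            logger.warning("sample %s dropped: %d reads < rarefaction depth %d",
                           sample, total, depth)
            continue
        cols[sample] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(cols, index=table.counts.index)
    return FeatureTable(counts, table.sequences)


def aggregate_taxa(
    table: FeatureTable,
    assignments: Mapping[str, TaxonomyAssignment],
    rank: str,
) -> FeatureTable:
    """Sum counts over features sharing the ``rank`` label; features not
    classified to that depth pool into "unclassified". Count-conserving."""
    if rank not in _RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    need = _RANK_DEPTH[rank]
    labels = []
    for fid in table.feature_ids:
        lin = assignments[fid].lineage
        labels.append(lin[need - 1] if len(lin) >= need else "unclassified")
    agg = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    return FeatureTable(agg, None)


def relative_abundance(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    counts = table.counts if isinstance(table, FeatureTable) else table
    return counts / counts.sum(axis=0)


# ---------------------------------------------------------------------------
# TSV / FASTA round-trips


def write_table(table: FeatureTable, counts_path, fasta_path=None) -> None:
    table.counts.rename_axis("feature_id").to_csv(counts_path, sep="\t")
    if fasta_path is not None and table.sequences is not None:
        from .io import write_fasta
        write_fasta(fasta_path, table.sequences)


def read_table(counts_path, fasta_path=None) -> FeatureTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    seqs = None
    if fasta_path is not None:
        from .io import read_fasta
        seqs = read_fasta(fasta_path)
    return FeatureTable(counts, seqs)


def read_reference_tsv(taxonomy_path, fasta_path) -> list[ReferenceRecord]:
    """Reference amplicons: FASTA plus TSV of (id, semicolon-ranked lineage)."""
    from .io import read_fasta
    seqs = read_fasta(fasta_path)
    df = pd.read_csv(taxonomy_path, sep="\t")
    out = []
    for _, row in df.iterrows():
        rid = str(row.iloc[0])
        lineage = tuple(part.strip() for part in str(row.iloc[1]).split(";"))
        if rid not in seqs:
            raise ValueError(f"reference {rid} missing from FASTA")
        out.append(ReferenceRecord(rid, lineage, seqs[rid]))
    return out
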