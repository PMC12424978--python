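"""Mock-community evaluation: expected composition under equal-mass gDNA
pooling, observed-vs-expected bias across replicate amplifications, and
theoretical-vs-observed ASV concordance.

Under equal-mass pooling of genomic DNA, the number of amplifiable rRNA
templates a strain contributes is proportional to its rRNA copy number
divided by its genome size, so the expected *read* proportion of taxon i is
(cᵢ/sᵢ) / Σⱼ(cⱼ/sⱼ). This amplicon-level basis is the default because read
proportions, not cell proportions, are what sequencing observes; a
genomic-DNA (genome-equivalents) basis is available by flag.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .census import TheoreticalASVRecord
from .profile import FeatureTable, TaxonomyAssignment


@dataclass(frozen=True)
class MockExpectation:
    taxon: str
    genome_size: int
    operon_copies: int
    expected_proportion: float


@dataclass(frozen=True)
class MockComparison:
    taxon: str
    expected: float
    observed_mean: float
    observed_sd: float
    n_replicates: int
    log2_bias: float


def load_mock_reference() -> pd.DataFrame:
    """Genome sizes and rRNA operon copy numbers of the eight-strain
    equal-mass DNA mock community (shipped reference table)."""
    ref = importlib.resources.files("longamp.data") / "zymo_d6305.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def expected_composition(
    genomes: pd.DataFrame | Iterable[tuple[str, int, int]],
    pooling: str = "equal_mass",
    basis: str = "amplicon",
) -> list[MockExpectation]:
    """Expected taxon proportions for an equal-mass gDNA pool.

    ``genomes``: DataFrame with columns (taxon, genome_size, operon_copies)
    or an iterable of such triples. ``basis='amplicon'`` weights by
    copies/size (read-level expectation); ``basis='gdna'`` weights by
    1/size (genome equivalents).
    """
    if pooling != "equal_mass":
        raise ValueError(f"unsupported pooling scheme {pooling!r}")
    if isinstance(genomes, pd.DataFrame):
        rows = list(genomes[["taxon", "genome_size", "operon_copies"]].itertuples(index=False))
    else:
        rows = list(genomes)
    if not rows:
        raise ValueError("no genomes given")
    taxa, sizes, copies = zip(*rows)
    sizes = np.asarray(sizes, dtype=float)
    copies = np.asarray(copies, dtype=float)
    if np.isnan(sizes).any() or (sizes <= 0).any():
        raise ValueError("genome sizes must be positive")
    if np.isnan(copies).any() or (copies < 1).any():
        raise ValueError("operon copy numbers must be >= 1")
    if basis == "amplicon":
        w = copies / sizes
    elif basis == "gdna":
        w = 1.0 / sizes
    else:
        raise ValueError(f"unknown basis {basis!r}")
    props = w / w.sum()
    return [
        MockExpectation(str(t), int(s), int(c), float(p))
        for t, s, c, p in zip(taxa, sizes, copies, props)
    ]


def compare_observed_expected(
    replicates: pd.DataFrame,
    expectations: Sequence[MockExpectation],
) -> pd.DataFrame:
    """Observed-vs-expected bias per taxon across replicate amplifications.

    ``replicates``: taxa × replicate relative-abundance table (columns are
    replicate samples; each column sums to ~1). Observed taxa with no
    expectation are pooled into an "other" row (expected 0, no log2 bias).
    Standard deviations use the n−1 denominator.
    """
    if replicates.shape[1] == 0:
        raise ValueError("need at least one replicate")
    exp_map = {e.taxon: e.expected_proportion for e in expectations}
    n = replicates.shape[1]
    known = [t for t in replicates.index if t in exp_map]
    other = replicates.drop(index=known).sum(axis=0)
    rows = []
    for e in expectations:
        obs = replicates.loc[e.taxon] if e.taxon in replicates.index else pd.Series(0.0, index=replicates.columns)
        mean = float(obs.mean())
        sd = float(obs.std(ddof=1)) if n > 1 else 0.0
        log2_bias = float(np.log2(mean / e.expected_proportion)) if mean > 0 else -np.inf
        rows.append({"taxon": e.taxon, "expected": e.expected_proportion,
                     "observed_mean": mean, "observed_sd": sd,
                     "n_replicates": n, "log2_bias": log2_bias})
    df = pd.DataFrame(rows)
    if float(other.sum()) > 0:
        df = pd.concat([df, pd.DataFrame([{
            "taxon": "other", "expected": 0.0,
            "observed_mean": float(other.mean()),
            "observed_sd": float(other.std(ddof=1)) if n > 1 else 0.0,
            "n_replicates": n, "log2_bias": np.nan,
        }])], ignore_index=True)
    return df


def recover_amplification_bias(comparison: pd.DataFrame, taxon: str) -> float:
    """Estimate the log2 amplification-bias fold of one taxon.

    Because proportions renormalize, log2(observed/expected) of a biased
    taxon under-states the planted fold; dividing by the median
    observed/expected ratio of the remaining taxa (which all share the
    renormalization factor) removes it, so the estimator recovers the fold
    itself.
    """
    df = comparison[comparison["taxon"] != "other"].set_index("taxon")
    ratios = df["observed_mean"] / df["expected"]
    baseline = float(ratios.drop(taxon).median())
    return float(np.log2(ratios[taxon] / baseline))


def asv_concordance(
    table: FeatureTable,
    assignments: Mapping[str, TaxonomyAssignment],
    theoretical: Sequence[TheoreticalASVRecord],
    rank: str = "strain",
) -> pd.DataFrame:
    """Observed distinct ASVs per taxon vs the theoretical count and the
    operon-copy census.

    A feature counts toward the taxon its assignment resolves to at
    ``rank`` (features not classified that deep are ignored here). Taxa
    with no observed feature report 0 against the census expectation.
    """
    from .profile import _RANK_DEPTH
    need = _RANK_DEPTH[rank]
    per_taxon: dict[str, set[str]] = {}
    for fid in table.feature_ids:
        lin = assignments[fid].lineage
        if len(lin) >= need:
            per_taxon.setdefault(lin[need - 1], set()).add(fid)
    rows = []
    for rec in theoretical:
        observed = len(per_taxon.get(rec.taxon, ()))
        rows.append({"taxon": rec.taxon, "design": rec.design,
                     "observed_asvs": observed,
                     "expected_asvs": rec.unique_amplicons,
                     "operon_copies": rec.operon_copies})
    return pd.DataFrame(rows)
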