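"""Synthetic genomes, communities, and amplicon reads with ground truth.

Generates bacterial genomes with a controlled rRNA-operon architecture —
multiple operon copies whose divergence is concentrated in the internal
transcribed spacer (ITS), optional strain-defining 16S markers, optional
non-contiguous operons (unrelated DNA inserted between 16S and 23S) —
plus two-cohort community designs with tunable taxon-abundance effects,
and error-free or noisy amplicon reads per design with per-read
provenance. Everything is deterministic given the seeds recorded in the
truth objects.

The 16S and 23S-prefix scaffolds are fixed synthetic sequences shipped as
package data, with the default designs' primer motifs embedded at the
canonical offsets (27F at 1, 515F/534R around 515-535, 806R around 787,
1492R at the 3' end, and a 23S reverse site ~530 bp into the 23S gene);
variant substitutions avoid the primer windows unless mismatch injection
is requested.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import GenomeRecord
from .primers import AmpliconDesign, in_silico_pcr, reverse_complement
from .profile import RANKS, ReferenceRecord

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# primer windows on the shipped scaffolds (0-based half-open)
SSU_PRIMER_WINDOWS = {
    "forward_27f": (0, 20),
    "reverse_534r": (515, 535),   # merged 515F / rc(534R) motif
    "reverse_806r": (787, 807),
    "reverse_1492r": (1519, 1538),
}
LSU_PRIMER_WINDOWS = {"strainid_reverse": (529, 550)}


def _load_scaffolds() -> tuple[str, str]:
    from .io import read_fasta
    ref = importlib.resources.files("longamp.data") / "operon_scaffold_synthetic.fasta"
    with importlib.resources.as_file(ref) as path:
        seqs = read_fasta(path)
    return seqs["SSU_scaffold"], seqs["LSU_scaffold"]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for p in positions:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class GenomeSpec:
    """Recipe for one synthetic genome.

    ``n_its_variants`` / ``n_16s_variants`` control intra-genome operon
    divergence (variants are assigned to copies round-robin);
    ``ssu_tag_mutations`` plants a strain-defining marker shared by every
    copy, confined to ``ssu_tag_region`` of the 16S; ``non_contiguous``
    inserts ``insertion_length`` bp of unrelated sequence between the ITS
    and the 23S gene of every copy. ``primer_site_mismatches`` mutates the
    centre of a named primer window (keys of SSU_PRIMER_WINDOWS /
    LSU_PRIMER_WINDOWS) to emulate primer-template mismatches.
    """

    name: str
    lineage: tuple[str, ...] | None = None
    genome_size: int = 60_000
    n_operons: int = 5
    n_16s_variants: int = 1
    n_its_variants: int = 1
    ssu_divergence: float = 0.005
    its_divergence: float = 0.02
    its_length: int | None = None          # default: drawn from 300-700 bp
    non_contiguous: bool = False
    insertion_length: int = 0
    ssu_tag_mutations: int = 0
    ssu_tag_region: tuple[int, int] = (50, 500)
    primer_site_mismatches: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_its_variants <= self.n_operons):
            raise ValueError("require 1 <= n_its_variants <= n_operons")
        if not (1 <= self.n_16s_variants <= self.n_operons):
            raise ValueError("require 1 <= n_16s_variants <= n_operons")
        if self.non_contiguous and self.insertion_length <= 0:
            raise ValueError("non_contiguous genomes need insertion_length > 0")


@dataclass
class SyntheticGenome:
    """A generated genome plus its machine-readable truth."""

    name: str
    lineage: tuple[str, ...]
    contigs: dict[str, str]
    annotations: list[dict]
    operons: list[dict]      # per-copy truth: coords, strand, variant ids
    spec: GenomeSpec

    def to_record(self) -> GenomeRecord:
        return GenomeRecord(self.name, self.contigs, self.annotations, self.lineage)

    def write(self, fasta_path, gff3_path) -> None:
        from .io import write_fasta, write_gff3
        write_fasta(fasta_path, self.contigs)
        write_gff3(gff3_path, self.annotations)


def _variant_set(base: str, n_variants: int, rate: float,
                 protected: Sequence[tuple[int, int]],
                 rng: np.random.Generator) -> list[str]:
    """Base sequence plus n_variants-1 derived variants, each mutating a
    disjoint block of allowed positions (guaranteeing pairwise distinctness)."""
    if n_variants == 1:
        return [base]
    mask = np.ones(len(base), dtype=bool)
    for s, e in protected:
        mask[s:e] = False
    allowed = rng.permutation(np.nonzero(mask)[0])
    k = max(1, round(rate * len(base)))
    if (n_variants - 1) * k > allowed.size:
        raise ValueError("divergence rate too high for the number of variants")
    out = [base]
    for v in range(1, n_variants):
        pos = allowed[(v - 1) * k: v * k]
        out.append(_mutate(base, pos, rng))
    return out


def generate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Random background with ``n_operons`` planted rRNA operons.

    Each operon is 16S (1,540 bp scaffold) + ITS (300-700 bp, genome-
    specific) + optional non-contiguity insertion + 23S prefix (900 bp
    scaffold); copies are planted on alternating strands. Truth
    annotations mark every part. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ssu_base, lsu_base = _load_scaffolds()

    # strain-defining 16S marker (shared by all copies)
    if spec.ssu_tag_mutations:
        s, e = spec.ssu_tag_region
        mask = np.zeros(len(ssu_base), dtype=bool)
        mask[s:e] = True
        for ws, we in SSU_PRIMER_WINDOWS.values():
            mask[ws:we] = False
        cand = np.nonzero(mask)[0]
        pos = rng.choice(cand, size=spec.ssu_tag_mutations, replace=False)
        ssu_base = _mutate(ssu_base, pos, rng)

    # primer-site mismatch injection (centred in the window, so counts stay
    # clear of the 3'-terminal exact-match bases on either strand)
    for site, k in spec.primer_site_mismatches.items():
        if site in SSU_PRIMER_WINDOWS:
            ws, we = SSU_PRIMER_WINDOWS[site]
            mid = (ws + we) // 2
            ssu_base = _mutate(ssu_base, range(mid - k // 2, mid - k // 2 + k), rng)
        elif site in LSU_PRIMER_WINDOWS:
            ws, we = LSU_PRIMER_WINDOWS[site]
            mid = (ws + we) // 2
            lsu_base = _mutate(lsu_base, range(mid - k // 2, mid - k // 2 + k), rng)
        else:
            raise ValueError(f"unknown primer site {site!r}")

    its_len = spec.its_length if spec.its_length is not None else int(rng.integers(300, 701))
    its_base = _rand_seq(rng, its_len)

    ssu_variants = _variant_set(ssu_base, spec.n_16s_variants, spec.ssu_divergence,
                                list(SSU_PRIMER_WINDOWS.values()), rng)
    its_variants = _variant_set(its_base, spec.n_its_variants, spec.its_divergence,
                                [], rng)
    insertion = _rand_seq(rng, spec.insertion_length) if spec.non_contiguous else ""

    op_len = len(ssu_base) + its_len + len(insertion) + len(lsu_base)
    margin = 250
    needed = spec.n_operons * (op_len + margin) + margin
    if needed > spec.genome_size:
        raise ValueError(
            f"{spec.n_operons} operons of {op_len} bp do not fit in "
            f"genome_size {spec.genome_size} (need >= {needed})")

    genome = np.frombuffer(_rand_seq(rng, spec.genome_size).encode(),
                           dtype=np.uint8).copy()
    contig = f"{spec.name}_chr"
    annotations: list[dict] = []
    operons: list[dict] = []
    slack = (spec.genome_size - needed) // max(spec.n_operons, 1)
    for i in range(spec.n_operons):
        off = margin + i * (op_len + margin + slack)
        strand = "+" if i % 2 == 0 else "-"
        sv, iv = i % spec.n_16s_variants, i % spec.n_its_variants
        parts = [("16S", ssu_variants[sv]), ("ITS", its_variants[iv])]
        if insertion:
            parts.append(("insertion", insertion))
        parts.append(("23S", lsu_base))
        op_seq = "".join(s for _, s in parts)
        planted = op_seq if strand == "+" else reverse_complement(op_seq)
        genome[off:off + op_len] = np.frombuffer(planted.encode(), dtype=np.uint8)

        coords = {}
        cursor = off if strand == "+" else off + op_len
        for label, s in parts:
            if strand == "+":
                coords[label] = (cursor, cursor + len(s))
                cursor += len(s)
            else:
                coords[label] = (cursor - len(s), cursor)
                cursor -= len(s)
        products = {"16S": "16S ribosomal RNA", "23S": "23S ribosomal RNA",
                    "ITS": "internal transcribed spacer"}
        for label in ("16S", "ITS", "23S"):
            s, e = coords[label]
            annotations.append({
                "contig": contig, "source": "longamp-sim",
                "type": "rRNA" if label != "ITS" else "misc_RNA",
                "start": s, "end": e, "strand": strand,
                "attributes": {"ID": f"{spec.name}_op{i}_{label}",
                               "product": products[label]},
            })
        operons.append({"index": i, "contig": contig, "strand": strand,
                        "coords": coords, "ssu_variant": sv, "its_variant": iv,
                        "non_contiguous": spec.non_contiguous})

    lineage = spec.lineage or default_lineage(spec.name)
    return SyntheticGenome(spec.name, lineage, {contig: genome.tobytes().decode()},
                           annotations, operons, spec)


def default_lineage(name: str) -> tuple[str, ...]:
    genus = name.split("_")[0]
    species = "_".join(name.split("_")[:2]) if "_" in name else f"{genus}_sp"
    return ("Bacteria", "SynthPhylum", "SynthClass", "SynthOrder",
            "SynthFamily", genus, species, name)


def reference_from_genomes(
    genomes: Sequence[SyntheticGenome],
    design: AmpliconDesign,
    pairing_ceiling: int = 10_000,
) -> list[ReferenceRecord]:
    """Reference amplicon set (full lineage per record) from the theoretical
    amplicons of a genome collection under one design."""
    refs = []
    for g in genomes:
        seqs = sorted({h.sequence for h in in_silico_pcr(g.contigs, design, g.name,
                                                         pairing_ceiling)
                       if h.passed_length_filter})
        for k, s in enumerate(seqs):
            refs.append(ReferenceRecord(f"{g.name}_amp{k + 1}", g.lineage, s))
    return refs


# ---------------------------------------------------------------------------
# communities


@dataclass
class CommunityTruth:
    """Ground truth for a simulated community: per-sample taxon proportions,
    cohort labels, and the effect that separates the cohorts."""

    proportions: pd.DataFrame    # samples × taxa
    cohorts: pd.Series           # sample -> cohort label
    base_composition: pd.Series
    effects: dict[str, float]
    seed: int | None


def generate_community(
    taxa: Sequence[str],
    n_per_cohort: int = 12,
    base_composition: Mapping[str, float] | None = None,
    effects: Mapping[str, float] | None = None,
    dirichlet_concentration: float | None = None,
    cohort_names: tuple[str, str] = ("cohortA", "cohortB"),
    seed: int | None = None,
) -> CommunityTruth:
    """Two-cohort community design with fold-change effects.

    Cohort-2 proportions are the base composition with ``effects`` folds
    applied to the named taxa, renormalized. Per-sample proportions equal
    the cohort proportions exactly, or are Dirichlet-drawn around them when
    ``dirichlet_concentration`` is set (larger = less overdispersion).
    """
    effects = dict(effects or {})
    if any(f <= 0 for f in effects.values()):
        raise ValueError("fold changes must be positive")
    if base_composition is None:
        base = pd.Series(1.0 / len(taxa), index=list(taxa))
    else:
        base = pd.Series(base_composition, dtype=float).reindex(list(taxa))
        if base.isna().any() or not math.isclose(base.sum(), 1.0, rel_tol=1e-6):
            raise ValueError("base_composition must cover all taxa and sum to 1")
    shifted = base.copy()
    for t, fold in effects.items():
        shifted[t] = shifted[t] * fold
    shifted = shifted / shifted.sum()

    rng = np.random.default_rng(seed)
    rows, idx, cohorts = [], [], []
    for cohort, props in zip(cohort_names, (base, shifted)):
        for i in range(n_per_cohort):
            if dirichlet_concentration is not None:
                p = rng.dirichlet(props.to_numpy() * dirichlet_concentration)
            else:
                p = props.to_numpy()
            rows.append(p)
            idx.append(f"{cohort}_{i + 1:02d}")
            cohorts.append(cohort)
    proportions = pd.DataFrame(rows, index=idx, columns=list(taxa))
    return CommunityTruth(proportions, pd.Series(cohorts, index=idx, name="cohort"),
                          base, effects, seed)


# ---------------------------------------------------------------------------
# reads


@dataclass
class ReadSet:
    """Simulated amplicon reads with per-read provenance."""

    reads: dict[str, list[str]]          # sample -> read sequences
    provenance: pd.DataFrame             # read_id, sample, taxon, operon_copy
    dropped_taxa: list[str]              # taxa with no amplifiable copy
    design: str
    seed: int | None

    def write_fastq(self, out_dir) -> None:
        from pathlib import Path
        from .io import write_fastq
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        by_sample = self.provenance.groupby("sample", sort=False)
        for sample, grp in by_sample:
            pairs = zip(grp["read_id"], self.reads[sample])
            write_fastq(out / f"{sample}.fastq", list(pairs))


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    return _mutate(seq, pos, rng)


def generate_reads(
    truth: CommunityTruth,
    genomes: Mapping[str, SyntheticGenome],
    design: AmpliconDesign,
    depth: int,
    error_rate: float = 0.0,
    seed: int | None = None,
    bias: Mapping[str, float] | None = None,
    pairing_ceiling: int = 10_000,
) -> ReadSet:
    """Draw ``depth`` reads per sample: taxon ~ sample proportions, operon
    copy uniform among the taxon's amplifiable copies, sequence = the
    design's insert with iid substitutions at ``error_rate``.

    Taxa with no amplifiable copy under the design drop out silently (their
    reads are omitted, emulating amplification dropout); ``bias`` applies
    per-taxon amplification fold-changes to the sampling proportions.
    """
    if not (0.0 <= error_rate <= 0.05):
        raise ValueError("error_rate must be in [0, 0.05]")
    rng = np.random.default_rng(seed)
    taxa = list(truth.proportions.columns)
    amplicons: dict[str, list[tuple[str, str]]] = {}
    dropped = []
    for t in taxa:
        g = genomes[t]
        hits = [h for h in in_silico_pcr(g.contigs, design, t, pairing_ceiling)
                if h.passed_length_filter]
        if hits:
            amplicons[t] = [(f"{h.contig}:{h.insert_start}", h.sequence) for h in hits]
        else:
            dropped.append(t)
            logger.info("taxon %s has no amplifiable copy under %s; reads omitted",
                        t, design.name)

    bias = dict(bias or {})
    reads: dict[str, list[str]] = {}
    prov_rows = []
    for sample in truth.proportions.index:
        props = truth.proportions.loc[sample].to_numpy(dtype=float).copy()
        for j, t in enumerate(taxa):
            props[j] *= bias.get(t, 1.0)
        props /= props.sum()
        taxon_counts = rng.multinomial(depth, props)
        sample_reads: list[str] = []
        k = 0
        for t, cnt in zip(taxa, taxon_counts):
            if cnt == 0 or t not in amplicons:
                continue
            copies = amplicons[t]
            copy_counts = rng.multinomial(cnt, np.full(len(copies), 1.0 / len(copies)))
            for (copy_id, seq), cc in zip(copies, copy_counts):
                for _ in range(cc):
                    read = seq if error_rate == 0.0 else _apply_errors(seq, error_rate, rng)
                    rid = f"{sample}_r{k + 1}"
                    k += 1
                    sample_reads.append(read)
                    prov_rows.append((rid, sample, t, copy_id))
        reads[sample] = sample_reads
    provenance = pd.DataFrame(prov_rows,
                              columns=["read_id", "sample", "taxon", "operon_copy"])
    return ReadSet(reads, provenance, dropped, design.name, seed)
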