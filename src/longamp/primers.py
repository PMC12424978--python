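"""Degenerate-primer matching and in-silico PCR.

Implements IUPAC-aware primer site finding on both strands, pairing of
forward/reverse sites into amplicon products, and derivation of nested
sub-amplicons from long reads by internal primer trimming (the basis of
like-for-like comparison between long ribosomal-operon amplicons and the
short 16S designs they contain).

Conventions
-----------
* Coordinates are 0-based half-open on the top strand internally; report
  writers convert to 1-based inclusive.
* Amplicon ``sequence`` is the inter-primer *insert* only (primer regions
  excluded), oriented 5'→3' from the forward primer.
* A template ``N`` matches no primer base (counts as a mismatch); primer
  degeneracy codes match their base set. Matching is asymmetric on purpose,
  mirroring physical annealing of a synthesized oligo to template DNA.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import yaml

# IUPAC nucleotide codes as 4-bit sets (A=1, C=2, G=4, T=8)
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# byte-indexed lookup tables
_PRIMER_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in IUPAC_BITS.items():
    _PRIMER_LUT[ord(_c)] = _b
    _PRIMER_LUT[ord(_c.lower())] = _b
_TEMPLATE_LUT = np.zeros(256, dtype=np.uint8)  # N and anything odd -> 0 (matches nothing)
for _c in "ACGT":
    _TEMPLATE_LUT[ord(_c)] = IUPAC_BITS[_c]
    _TEMPLATE_LUT[ord(_c.lower())] = IUPAC_BITS[_c]

# complement of a 4-bit base set: swap A<->T and C<->G bits
_BIT_COMP = np.array(
    [((b & 1) << 3) | ((b & 8) >> 3) | ((b & 2) << 1) | ((b & 4) >> 1) for b in range(16)],
    dtype=np.uint8,
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _validate_iupac(s: str, what: str) -> None:
    bad = set(s.upper()) - IUPAC_BITS.keys()
    if not s:
        raise ValueError(f"{what} is empty")
    if bad:
        raise ValueError(f"{what} contains non-IUPAC characters: {sorted(bad)}")


def iupac_match_count(pattern: str, window: str) -> int:
    """Number of positions where ``window`` (A/C/G/T) falls outside the
    degeneracy set of the corresponding ``pattern`` IUPAC code."""
    if len(pattern) != len(window):
        raise ValueError(f"length mismatch: pattern {len(pattern)} vs window {len(window)}")
    _validate_iupac(pattern, "pattern")
    if set(window.upper()) - set("ACGT"):
        raise ValueError("window must contain only A/C/G/T")
    pat = _PRIMER_LUT[np.frombuffer(pattern.encode(), dtype=np.uint8)]
    win = _TEMPLATE_LUT[np.frombuffer(window.encode(), dtype=np.uint8)]
    return int(np.count_nonzero((pat & win) == 0))


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with its matching policy.

    ``reverse`` is given as synthesized (5'→3'), i.e. it is the reverse
    complement of the top-strand window it binds.
    """

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 2
    require_terminal_match: int = 3

    def __post_init__(self) -> None:
        _validate_iupac(self.forward, f"{self.name} forward primer")
        _validate_iupac(self.reverse, f"{self.name} reverse primer")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        if self.max_mismatch >= min(len(self.forward), len(self.reverse)):
            raise ValueError("max_mismatch must be smaller than the primer length")


@dataclass(frozen=True)
class AmpliconDesign:
    """A named primer pair plus length-bound policy defining one amplicon type."""

    primers: PrimerPair
    min_length: int
    max_length: int
    region_label: str = "custom"

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("require 0 < min_length <= max_length")

    @property
    def name(self) -> str:
        return self.primers.name


@dataclass(frozen=True)
class PrimerHit:
    """One primer binding site; ``position`` is the leftmost (5'-most on the
    top strand) template base of the matched window."""

    contig: str
    position: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class AmpliconHit:
    """One in-silico PCR product (insert-only coordinates and sequence)."""

    genome: str
    contig: str
    insert_start: int
    insert_end: int
    length: int
    fwd_mismatches: int
    rev_mismatches: int
    sequence: str
    passed_length_filter: bool
    strand: str = "+"


def _mismatch_profile(tpl_bits: np.ndarray, pat_bits: np.ndarray) -> np.ndarray:
    """Mismatch count of ``pat_bits`` at every offset of ``tpl_bits``."""
    n = tpl_bits.size - pat_bits.size + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int32)
    mism = np.zeros(n, dtype=np.int32)
    for j, pb in enumerate(pat_bits):
        mism += (tpl_bits[j:j + n] & pb) == 0
    return mism


def find_primer_sites(
    contig: str,
    primer: str,
    max_mismatch: int = 2,
    terminal_exact: int = 3,
    contig_name: str = "contig",
) -> list[PrimerHit]:
    """All binding sites of a degenerate primer on both strands.

    A ``-`` strand hit means the primer matches the reverse complement of the
    top strand; its ``position`` is still the leftmost top-strand base of the
    window. The ``terminal_exact`` 3'-terminal primer bases must be
    mismatch-free (the 3' end drives polymerase extension).
    """
    if not contig:
        raise ValueError("contig is empty")
    _validate_iupac(primer, "primer")
    tpl = _TEMPLATE_LUT[np.frombuffer(contig.encode(), dtype=np.uint8)]
    pat = _PRIMER_LUT[np.frombuffer(primer.upper().encode(), dtype=np.uint8)]
    pat_rc = _BIT_COMP[pat][::-1]
    t = min(terminal_exact, len(primer))

    hits: list[PrimerHit] = []
    for strand, bits in (("+", pat), ("-", pat_rc)):
        mism = _mismatch_profile(tpl, bits)
        # 3' terminal window: last t pattern bases on '+', first t on '-'
        term = bits[len(bits) - t:] if strand == "+" else bits[:t]
        n = mism.size
        term_off = len(primer) - t if strand == "+" else 0
        term_mism = np.zeros(n, dtype=np.int32)
        for j, pb in enumerate(term):
            term_mism += (tpl[term_off + j:term_off + j + n] & pb) == 0
        for pos in np.nonzero((mism <= max_mismatch) & (term_mism == 0))[0]:
            hits.append(PrimerHit(contig_name, int(pos), strand, int(mism[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _pair_hits(
    seq: str,
    design: AmpliconDesign,
    contig_name: str,
    genome: str,
    pairing_ceiling: int,
    strand: str,
) -> list[AmpliconHit]:
    """Pair forward '+' sites with nearest downstream reverse '-' sites on one
    orientation of a contig (coordinates local to ``seq``)."""
    p = design.primers
    fwd = [h for h in find_primer_sites(seq, p.forward, p.max_mismatch,
                                        p.require_terminal_match, contig_name)
           if h.strand == "+"]
    rev = [h for h in find_primer_sites(seq, p.reverse, p.max_mismatch,
                                        p.require_terminal_match, contig_name)
           if h.strand == "-"]
    if not fwd or not rev:
        return []
    rev_starts = np.array([h.position for h in rev])
    out = []
    flen = len(p.forward)
    for fh in fwd:
        ins_start = fh.position + flen
        k = int(np.searchsorted(rev_starts, ins_start))
        if k == len(rev):
            continue
        ins_end = int(rev_starts[k])
        length = ins_end - ins_start
        if length > pairing_ceiling:
            continue
        out.append(AmpliconHit(
            genome=genome, contig=contig_name,
            insert_start=ins_start, insert_end=ins_end, length=length,
            fwd_mismatches=fh.mismatches, rev_mismatches=rev[k].mismatches,
            sequence=seq[ins_start:ins_end],
            passed_length_filter=design.min_length <= length <= design.max_length,
            strand=strand,
        ))
    return out


def in_silico_pcr(
    genome: Mapping[str, str],
    design: AmpliconDesign,
    genome_label: str = "genome",
    pairing_ceiling: int = 10_000,
) -> list[AmpliconHit]:
    """In-silico PCR of a primer-pair design over a set of contigs.

    Products are sought in both orientations (forward primer on either
    strand); each forward site is paired with its nearest downstream reverse
    site within ``pairing_ceiling`` bp of insert. Products outside the
    design's length bounds are emitted with ``passed_length_filter=False``
    rather than dropped, so over-long products (non-contiguous operons) are
    observed and then filtered.
    """
    hits: list[AmpliconHit] = []
    for cname, seq in genome.items():
        hits.extend(_pair_hits(seq, design, cname, genome_label, pairing_ceiling, "+"))
        L = len(seq)
        for h in _pair_hits(reverse_complement(seq), design, cname, genome_label,
                            pairing_ceiling, "-"):
            # map local rc coordinates back to top-strand
            h.insert_start, h.insert_end = L - h.insert_end, L - h.insert_start
            hits.append(h)
    hits.sort(key=lambda h: (h.contig, h.insert_start, h.strand))
    return hits


def trim_to_subregion(read: str, sub_design: AmpliconDesign,
                      assume_shared_forward: bool = False) -> str | None:
    """Excise a nested sub-amplicon from a long amplicon read.

    The read must be oriented 5'→3' from its parent design's forward primer.
    Returns the inter-primer insert of ``sub_design``, or None when either
    internal primer site is absent within the design's mismatch budget. With
    multiple candidate sites, the 5'-most forward site and its nearest
    compatible reverse site are used.

    Primer-free reads (inserts) from a parent design that *shares* the
    sub-design's forward primer carry no internal forward site; with
    ``assume_shared_forward=True`` the read's 5' end is then taken as the
    forward boundary (only the internal reverse site is required). This is
    how nested 16S datasets are derived in-silico from long-operon reads.
    """
    if not read:
        return None
    products = _pair_hits(read, sub_design, "read", "read", len(read), "+")
    if products:
        best = min(products, key=lambda h: (h.insert_start, h.insert_end))
        return best.sequence
    if assume_shared_forward:
        p = sub_design.primers
        rev = [h for h in find_primer_sites(read, p.reverse, p.max_mismatch,
                                            p.require_terminal_match)
               if h.strand == "-"]
        if rev:
            return read[:rev[0].position]
    return None


# ---------------------------------------------------------------------------
# shipped default designs


def _load_design_config(path=None) -> dict:
    if path is None:
        ref = importlib.resources.files("longamp.data") / "designs.yaml"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def load_designs(path=None) -> dict[str, AmpliconDesign]:
    """Load amplicon designs from a YAML config (shipped defaults if None)."""
    cfg = _load_design_config(path)
    defaults = cfg.get("defaults", {})
    mm = defaults.get("max_mismatch", 2)
    te = defaults.get("terminal_exact", 3)
    out = {}
    for name, d in cfg["designs"].items():
        pair = PrimerPair(
            name=name, forward=d["forward"], reverse=d["reverse"],
            max_mismatch=d.get("max_mismatch", mm),
            require_terminal_match=d.get("terminal_exact", te),
        )
        out[name] = AmpliconDesign(
            primers=pair, min_length=d["min_length"], max_length=d["max_length"],
            region_label=name if name in {"V1V3", "V4", "FULL16S", "STRAINID"} else "custom",
        )
    return out


def default_designs() -> dict[str, AmpliconDesign]:
    return load_designs(None)


def default_pairing_ceiling() -> int:
    return _load_design_config(None).get("defaults", {}).get("pairing_ceiling", 10_000)
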