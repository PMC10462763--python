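"""Promoter window extraction, PWM scanning and differential motif enrichment.

A transcription-factor binding motif is modelled as a position frequency
matrix (PFM).  With a pseudocount ``c`` and background distribution ``b`` the
per-position probability of base ``j`` at column ``i`` is

    p_ij = (n_ij + c) / (N_i + 4c)

and scanning uses the log2-odds score ``sum_i log2(p_i,x_i / b_x_i)`` over a
window, on both strands.  Differential enrichment between a primary and a
control promoter set counts, per motif, the sequences containing at least one
hit and compares the two proportions with a one-sided Fisher exact test,
Benjamini-Hochberg adjusted across motifs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats

from ._util import PromdivergeError, reverse_complement
from .meta import bh_adjust

__all__ = [
    "MotifMatrix",
    "MotifHit",
    "PromoterRecord",
    "EnrichmentRecord",
    "parse_motif_file",
    "write_motif_file",
    "extract_promoter_window",
    "scan_sequence",
    "differential_enrichment",
    "builtin_motifs",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MotifMatrix:
    """Position frequency matrix with derived probability and log-odds forms.

    ``counts`` has shape (4, width), rows in A, C, G, T order.  The background
    defaults to uniform; the pseudocount (default 0.5) is added per cell
    before normalising, so every column of the probability matrix sums to 1.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise PromdivergeError(f"motif {self.name!r}: counts must be 4 x width")
        if (counts < 0).any():
            raise PromdivergeError(f"motif {self.name!r}: negative counts")
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
            raise PromdivergeError(f"motif {self.name!r}: invalid background")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        num = self.counts + self.pseudocount
        return num / num.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """4 x width log2-odds matrix against the background."""
        bg = np.asarray(self.background, dtype=float)[:, None]
        return np.log2(self.probabilities / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probabilities.argmax(axis=0))

    def sample_site(self, rng: np.random.Generator,
                    min_score_fraction: float | None = None) -> str:
        """Draw one binding-site instance from the column probabilities.

        With ``min_score_fraction`` set, rejection-samples until the instance
        scores at least that fraction of the maximum log2-odds — a functional
        (high-affinity) site rather than an arbitrary draw.
        """
        p = self.probabilities
        lom = self.log_odds
        floor = (-np.inf if min_score_fraction is None
                 else min_score_fraction * self.max_score)
        for _ in range(1000):
            idx = [rng.choice(4, p=p[:, i]) for i in range(self.width)]
            if sum(lom[j, i] for i, j in enumerate(idx)) >= floor:
                return "".join(_BASES[j] for j in idx)
        return self.consensus  # unreachable for any sane floor


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based on the forward string
    strand: str  # "+" or "-"
    score: float
    matched: str


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter window read upstream-to-downstream relative to its TSS."""

    gene_id: str
    chrom: str
    start: int  # genomic, 0-based half-open
    end: int
    strand: str
    sequence: str
    tss_offset: int  # index in `sequence` of the TSS base
    clipped: bool = False


@dataclass(frozen=True)
class EnrichmentRecord:
    motif: str
    a: int  # primary sequences with >=1 hit
    n1: int
    b: int  # control sequences with >=1 hit
    n2: int
    ratio: float
    p: float
    q: float = float("nan")
    significant: bool = False
    warning: str = ""


def parse_motif_file(text: str, pseudocount: float = 0.5) -> list[MotifMatrix]:
    """Parse motifs from JASPAR PFM text into :class:`MotifMatrix` objects.

    Accepts the JASPAR dialect (``>ID name`` headers followed by four count
    rows, with or without ``A [ ... ]`` row labels).
    """
    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:  # ragged rows, bad labels etc.
        raise PromdivergeError(f"motif parse error: {exc}") from exc
    out: list[MotifMatrix] = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in _BASES], dtype=float)
        if (counts < 0).any():
            raise PromdivergeError(f"motif parse error: negative counts in {rec.name}")
        name = rec.name or rec.matrix_id
        out.append(MotifMatrix(name=name, counts=counts, pseudocount=pseudocount))
    if not out:
        raise PromdivergeError("motif parse error: no records found")
    return out


def write_motif_file(motifs_: Iterable[MotifMatrix]) -> str:
    """Serialise motifs in the JASPAR PFM dialect (inverse of parse)."""
    chunks = []
    for m in motifs_:
        lines = [f">{m.name} {m.name}"]
        for i, base in enumerate(_BASES):
            row = " ".join(f"{v:g}" for v in m.counts[i])
            lines.append(f"{base} [ {row} ]")
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


def extract_promoter_window(
    gene_id: str,
    chrom: str,
    tss: int,
    strand: str,
    contigs: Mapping[str, str],
    upstream: int,
    downstream: int,
) -> PromoterRecord:
    """Extract the promoter window around a 0-based TSS.

    Plus strand: genomic interval ``[tss - upstream, tss + downstream)`` taken
    as-is.  Minus strand: ``[tss - downstream + 1, tss + upstream + 1)``
    reverse-complemented, so the returned string always reads upstream to
    downstream with the TSS base at index ``upstream``.  Windows clipped at
    contig edges are flagged.
    """
    if upstream < 0 or downstream < 0:
        raise PromdivergeError("upstream/downstream must be non-negative")
    if strand not in "+-":
        raise PromdivergeError(f"invalid strand {strand!r}")
    if chrom not in contigs:
        raise PromdivergeError(f"unknown contig {chrom!r}")
    contig = contigs[chrom]
    if not (0 <= tss < len(contig)):
        raise PromdivergeError(f"TSS {tss} outside contig {chrom!r}")
    if strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream + 1, tss + upstream + 1
    cstart, cend = max(0, start), min(len(contig), end)
    clipped = (cstart != start) or (cend != end)
    seq = contig[cstart:cend].upper()
    if strand == "-":
        seq = reverse_complement(seq)
        tss_offset = cend - 1 - tss
    else:
        tss_offset = tss - cstart
    return PromoterRecord(
        gene_id=gene_id, chrom=chrom, start=cstart, end=cend, strand=strand,
        sequence=seq, tss_offset=tss_offset, clipped=clipped,
    )


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T -> 0..3 and anything else (N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _strand_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score every window start for a 5-row log-odds matrix (row 4 = N = 0)."""
    w = lom.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for i in range(w):
        scores += lom[codes[i : i + n_win], i]
    return scores


def scan_sequence(
    seq: str,
    motif: MotifMatrix,
    threshold: float | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """All motif occurrences on both strands with log2-odds >= threshold.

    ``N`` bases score as background (0 log-odds contribution).  The default
    threshold is 80% of the motif's maximum achievable score.  Hits are
    sorted by start, then strand (+ before -).
    """
    if threshold is None:
        threshold = 0.8 * motif.max_score
    if not np.isfinite(threshold):
        raise PromdivergeError("threshold must be finite")
    w = motif.width
    if len(seq) < w:
        return []
    lom = np.vstack([motif.log_odds, np.zeros((1, w))])  # row 4: N scores 0
    codes = _encode(seq)
    hits: list[MotifHit] = []
    fwd = _strand_scores(codes, lom)
    # reverse strand: score the reverse complement, map start s' -> L - w - s'
    rc_codes = _encode(reverse_complement(seq))
    rev = _strand_scores(rc_codes, lom)
    L = len(seq)
    for s in np.nonzero(fwd >= threshold)[0]:
        hits.append(MotifHit(sequence_id, int(s), "+", float(fwd[s]), seq[s : s + w].upper()))
    for s in np.nonzero(rev >= threshold)[0]:
        start = L - w - int(s)
        hits.append(MotifHit(sequence_id, start, "-", float(rev[s]), seq[start : start + w].upper()))
    hits.sort(key=lambda h: (h.start, 0 if h.strand == "+" else 1))
    return hits


def differential_enrichment(
    primary: Sequence[PromoterRecord] | Sequence[str],
    control: Sequence[PromoterRecord] | Sequence[str],
    motifs_: Sequence[MotifMatrix],
    threshold_fraction: float = 0.8,
    q_threshold: float = 0.05,
    ratio_pseudocount: float = 0.1,
) -> list[EnrichmentRecord]:
    """Per-motif presence/absence enrichment of primary vs control promoters.

    A sequence counts as positive when it carries at least one hit at
    ``threshold_fraction`` of the motif's maximum log2-odds score.  Per motif
    a one-sided Fisher exact test (enrichment direction) is computed on the
    2x2 presence table, with BH adjustment across motifs and the smoothed
    enrichment ratio ((a+c)/(n1+2c)) / ((b+c)/(n2+2c)).
    """
    if not primary or not control:
        raise PromdivergeError("primary and control sets must be non-empty")
    prim = [p.sequence if isinstance(p, PromoterRecord) else p for p in primary]
    ctrl = [p.sequence if isinstance(p, PromoterRecord) else p for p in control]
    n1, n2 = len(prim), len(ctrl)
    records: list[EnrichmentRecord] = []
    for m in motifs_:
        min_len = min(min(len(s) for s in prim), min(len(s) for s in ctrl))
        warning = "" if m.width <= min_len else "motif wider than shortest sequence"
        thr = threshold_fraction * m.max_score
        a = sum(bool(scan_sequence(s, m, thr)) for s in prim)
        b = sum(bool(scan_sequence(s, m, thr)) for s in ctrl)
        table = np.array([[a, n1 - a], [b, n2 - b]])
        p = float(stats.fisher_exact(table, alternative="greater")[1])
        c = ratio_pseudocount
        ratio = ((a + c) / (n1 + 2 * c)) / ((b + c) / (n2 + 2 * c))
        records.append(EnrichmentRecord(m.name, a, n1, b, n2, float(ratio), p, warning=warning))
    qs = bh_adjust([r.p for r in records])
    return [
        EnrichmentRecord(r.motif, r.a, r.n1, r.b, r.n2, r.ratio, r.p,
                         q=float(q), significant=bool(q <= q_threshold), warning=r.warning)
        for r, q in zip(records, qs)
    ]


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


# Idealised count matrices around the published consensus sites of the three
# promoter factors examined (AP1 TGA(C/G)TCA; the ETS factor SPI1/PU.1 purine
# box; the SP1 GC box).  Hand-written approximations, not database exports.
_BUILTIN_COUNTS = {
    "AP1": [
        #  A   T   G   A  C/G  T   C   A   T   C   C  (TRE with flanks)
        [70, 3, 1, 97, 2, 0, 3, 94, 4, 8, 10],
        [10, 2, 1, 1, 48, 2, 93, 2, 6, 75, 70],
        [12, 2, 97, 1, 46, 1, 2, 2, 5, 9, 12],
        [8, 93, 1, 1, 4, 97, 2, 2, 85, 8, 8],
    ],
    "SPI1": [
        #  A   G   A   G   G   A   A   G   T
        [60, 5, 80, 2, 1, 97, 97, 10, 15],
        [15, 5, 5, 1, 1, 1, 1, 10, 20],
        [15, 85, 10, 96, 97, 1, 1, 70, 15],
        [10, 5, 5, 1, 1, 1, 1, 10, 50],
    ],
    "SP1": [
        #  G   G   G   G   C   G   G   G   G   C
        [5, 2, 2, 2, 5, 2, 2, 2, 5, 10],
        [10, 3, 3, 3, 85, 3, 3, 3, 10, 60],
        [80, 92, 92, 92, 5, 92, 92, 92, 80, 10],
        [5, 3, 3, 3, 5, 3, 3, 3, 5, 20],
    ],
}


def builtin_motifs() -> dict[str, MotifMatrix]:
    """The three bundled promoter-factor motifs (AP1, SPI1/ETS, SP1)."""
    return {
        name: MotifMatrix(name=name, counts=np.array(rows, dtype=float))
        for name, rows in _BUILTIN_COUNTS.items()
    }
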