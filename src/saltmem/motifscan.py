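"""PWM promoter scanning with exact score-distribution p-values.

Motifs are position weight matrices read from MEME minimal format.  Each
window of a promoter is scored as the sum over columns of
``log2(p[base, j] / background[base])`` (bits).  Scores are integer-scaled
at 1/1000 bit per cell, and the exact distribution of the integer score of
a random background word is computed by column-wise convolution, giving an
exact p-value ``P(score >= s)`` for every attainable score — the same
construction used by exact-p-value motif scanners.

Promoters are the 1-kb regions immediately upstream of each gene's
transcription start site, extracted strand-aware from a genome FASTA and a
GFF3 annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: integer score units per bit
SCALE = 1000
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_P_THRESHOLD = 1e-4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A PWM with background model and exact score distribution.

    ``probs`` is a 4 x w matrix (rows A, C, G, T) built from counts with
    pseudocount ``epsilon``; ``int_scores`` holds the log2-odds scores
    scaled to integers (1/1000 bit granularity).
    """

    name: str
    probs: np.ndarray
    background: np.ndarray
    epsilon: float = DEFAULT_PSEUDOCOUNT
    int_scores: np.ndarray = field(init=False, repr=False)
    _pmf: np.ndarray = field(init=False, repr=False)
    _sf: np.ndarray = field(init=False, repr=False)
    _offset: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("probability matrix must have 4 rows (A, C, G, T)")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name!r}: columns do not sum to 1")
        with np.errstate(divide="ignore"):
            logodds = np.log2(self.probs / self.background[:, None])
        # zero-probability cells (possible only at pseudocount 0) are capped
        # at -20 bits; any window touching one scores far below threshold
        logodds = np.maximum(logodds, -20.0)
        self.int_scores = np.rint(SCALE * logodds).astype(np.int64)
        self._build_distribution()

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        background: np.ndarray | None = None,
        epsilon: float = DEFAULT_PSEUDOCOUNT,
    ) -> "MotifModel":
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        nsites = counts.sum(axis=0)
        probs = (counts + epsilon * background[:, None]) / (nsites + epsilon)
        return cls(name=name, probs=probs, background=background, epsilon=epsilon)

    @classmethod
    def from_consensus(
        cls, name: str, consensus: str, background: np.ndarray | None = None,
        nsites: int = 20, epsilon: float = DEFAULT_PSEUDOCOUNT,
    ) -> "MotifModel":
        counts = np.zeros((4, len(consensus)))
        for j, base in enumerate(consensus.upper()):
            counts[_IDX[base], j] = nsites
        return cls.from_counts(name, counts, background, epsilon)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def max_score(self) -> int:
        return int(self.int_scores.max(axis=0).sum())

    # ------------------------------------------------- score distribution
    def _build_distribution(self) -> None:
        """Exact pmf of the integer score of a random background word,
        by convolving one column at a time."""
        col_min = self.int_scores.min(axis=0)
        col_max = self.int_scores.max(axis=0)
        self._offset = int(col_min.sum())
        size = int((col_max - col_min).sum()) + 1
        pmf = np.zeros(size)
        pmf[0] = 1.0
        reach = 0
        for j in range(self.width):
            shifts = self.int_scores[:, j] - col_min[j]
            width_j = int(col_max[j] - col_min[j])
            new = np.zeros(size)
            for b in range(4):
                s = int(shifts[b])
                new[s : s + reach + 1] += self.background[b] * pmf[: reach + 1]
            pmf = new
            reach += width_j
        self._pmf = pmf
        self._sf = np.cumsum(pmf[::-1])[::-1]

    def score_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """(integer scores, probabilities) of the exact null distribution."""
        scores = np.arange(self._pmf.size) + self._offset
        return scores, self._pmf.copy()

    def pvalue(self, int_score: int | np.ndarray):
        """P(score >= s) under the background model, exact."""
        idx = np.asarray(int_score) - self._offset
        idx = np.clip(idx, 0, self._sf.size - 1)
        out = np.where(np.asarray(int_score) > self.max_score, 0.0, self._sf[idx])
        return float(out) if np.isscalar(int_score) else out


def read_meme(path) -> list[MotifModel]:
    """Parse a MEME minimal-format motif file into MotifModel objects.

    The file's background letter frequencies are used when present,
    otherwise a uniform background.  Malformed probability matrices raise
    with the offending motif's name.
    """
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    models = []
    for m in records:
        bg = np.array([m.background.get(b, 0.25) for b in ALPHABET], dtype=float)
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float)
        nsites = counts.sum(axis=0)
        if (nsites <= 0).any():
            raise ValueError(f"motif {m.name!r}: empty probability column")
        if not np.allclose(counts.sum(axis=0) / nsites[0], 1.0, atol=2e-2):
            raise ValueError(f"motif {m.name!r}: matrix rows do not sum to 1")
        models.append(MotifModel.from_counts(m.name, counts, background=bg))
    return models


def write_meme(models_or_consensi, path, background=None, nsites: int = 20) -> None:
    """Write motifs (MotifModel objects, or a mapping name -> consensus
    string) to MEME minimal format."""
    if background is None:
        background = np.full(4, 0.25)
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {background[i]:.5f}" for i, b in enumerate(ALPHABET)),
        "",
    ]
    if isinstance(models_or_consensi, dict):
        items = [
            (name, _consensus_probs(word)) for name, word in models_or_consensi.items()
        ]
    else:
        items = [(m.name, m.probs) for m in models_or_consensi]
    for name, probs in items:
        w = probs.shape[1]
        lines.append(f"MOTIF {name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {w} nsites= {nsites} E= 0"
        )
        for j in range(w):
            lines.append(" ".join(f"{probs[i, j]:.6f}" for i in range(4)))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def _consensus_probs(word: str) -> np.ndarray:
    probs = np.zeros((4, len(word)))
    for j, base in enumerate(word.upper()):
        probs[_IDX[base], j] = 1.0
    return probs


# ---------------------------------------------------------------- promoters
@dataclass(frozen=True)
class PromoterRecord:
    """One extracted promoter: sequence plus its genomic provenance
    (1-based inclusive interval on the source contig; ``strand`` is the
    gene's strand, and the sequence reads 5'->3' toward the TSS)."""

    gene: str
    seq: str
    contig: str
    start: int
    end: int
    strand: str


def extract_promoters(fasta_path, gff_path, length: int = 1000) -> dict[str, PromoterRecord]:
    """Extract the ``length``-bp region upstream of each gene's TSS.

    A + strand gene starting at S yields [max(1, S - length), S - 1]; a
    - strand gene ending at E yields [E + 1, min(contig_end, E + length)],
    reverse-complemented.  Genes whose promoter interval is empty (TSS at a
    contig edge) are skipped with a warning.
    """
    genome = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    promoters: dict[str, PromoterRecord] = {}
    for gene_id, contig, start, end, strand in _gff_genes(gff_path):
        if contig not in genome:
            raise ValueError(f"gene {gene_id!r} is on missing contig {contig!r}")
        contig_len = len(genome[contig])
        if strand == "-":
            p_start, p_end = end + 1, min(contig_len, end + length)
        else:
            p_start, p_end = max(1, start - length), start - 1
        if p_start > p_end:
            warnings.warn(f"gene {gene_id!r}: empty promoter interval, skipped")
            continue
        seq = str(genome[contig][p_start - 1 : p_end])
        if strand == "-":
            seq = reverse_complement(seq)
        promoters[gene_id] = PromoterRecord(
            gene=gene_id, seq=seq, contig=contig, start=p_start, end=p_end, strand=strand
        )
    return promoters


def _gff_genes(gff_path):
    """Yield (gene_id, contig, start, end, strand) for gene features of a
    GFF3 file (1-based inclusive coordinates)."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 row at line {lineno}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            gene_id = None
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if gene_id is None:
                raise ValueError(f"gene feature without ID at line {lineno}")
            yield gene_id, contig, int(start), int(end), strand


def write_promoters_fasta(promoters: dict[str, PromoterRecord], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(promoters):
            p = promoters[gene]
            fh.write(f">{gene} {p.contig}:{p.start}-{p.end}({p.strand})\n")
            for i in range(0, len(p.seq), 80):
                fh.write(p.seq[i : i + 80] + "\n")


def read_promoters_fasta(path) -> dict[str, PromoterRecord]:
    promoters: dict[str, PromoterRecord] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seq = "".join(chunks)
                    promoters[name] = PromoterRecord(name, seq, name, 1, len(seq), "+")
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.strip().upper())
    if name is not None:
        seq = "".join(chunks)
        promoters[name] = PromoterRecord(name, seq, name, 1, len(seq), "+")
    return promoters


# ---------------------------------------------------------------- scanning
@dataclass(frozen=True)
class MotifHit:
    """One PWM match: 0-based offset within the promoter (forward
    coordinates regardless of hit strand), score in bits, exact p-value."""

    gene: str
    offset: int
    strand: str
    score: float
    pvalue: float


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for base, i in _IDX.items():
        out[arr == ord(base)] = i
    return out


def _window_scores(enc: np.ndarray, int_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer score of every window, plus a validity mask (no N)."""
    w = int_scores.shape[1]
    n_win = enc.size - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    lut = np.vstack([int_scores, np.zeros((1, w), dtype=np.int64)])
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    scores = lut[windows, np.arange(w)].sum(axis=1)
    valid = ~(windows == 4).any(axis=1)
    return scores, valid


def scan(
    motif: MotifModel,
    promoters,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan promoters for motif matches with exact p-value < ``p_threshold``.

    Every offset on the forward strand (and the reverse complement when
    ``both_strands``) is scored; windows containing N are skipped.  Hits are
    sorted by gene, then offset, then strand.  ``promoters`` maps gene ->
    PromoterRecord or plain sequence string.
    """
    hits: list[MotifHit] = []
    w = motif.width
    for gene in sorted(promoters):
        rec = promoters[gene]
        seq = rec.seq if isinstance(rec, PromoterRecord) else str(rec)
        if len(seq) < w:
            continue
        strands = [("+", seq)]
        if both_strands:
            strands.append(("-", reverse_complement(seq)))
        for strand, s in strands:
            enc = _encode(s)
            scores, valid = _window_scores(enc, motif.int_scores)
            if scores.size == 0:
                continue
            pvals = motif.pvalue(scores)
            keep = valid & (pvals < p_threshold)
            for q in np.nonzero(keep)[0]:
                offset = int(q) if strand == "+" else len(seq) - w - int(q)
                hits.append(
                    MotifHit(
                        gene=gene,
                        offset=offset,
                        strand=strand,
                        score=scores[q] / SCALE,
                        pvalue=float(pvals[q]),
                    )
                )
    hits.sort(key=lambda h: (h.gene, h.offset, h.strand))
    return hits


def targets_of(hits: list[MotifHit]) -> set:
    """Genes with at least one surviving hit."""
    return {h.gene for h in hits}


@dataclass
class OverlapTable:
    """Upset-style overlap of named target sets: per-membership-pattern
    counts plus the intersection common to all sets."""

    names: tuple
    patterns: dict
    common: tuple
    union: tuple

    @property
    def n_common(self) -> int:
        return len(self.common)


def overlap_table(named_sets: dict) -> OverlapTable:
    names = tuple(named_sets)
    union = set().union(*named_sets.values()) if named_sets else set()
    patterns: dict[tuple, int] = {}
    for gene in union:
        pat = tuple(int(gene in named_sets[n]) for n in names)
        patterns[pat] = patterns.get(pat, 0) + 1
    common = set.intersection(*map(set, named_sets.values())) if named_sets else set()
    return OverlapTable(
        names=names,
        patterns=patterns,
        common=tuple(sorted(common, key=str)),
        union=tuple(sorted(union, key=str)),
    )
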