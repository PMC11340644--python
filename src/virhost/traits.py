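"""Genomic-trait features: composition counting and the trait vector S.

RNA viruses tend to mimic the trait usage of their hosts, so normalized usage
preferences of nucleotides, dinucleotides, codons and amino acids carry host
signal.  A genome is encoded as a fixed-length real vector of log2-transformed
preferences:

* nucleotide preference          ``P_x   = n_x / sum_x n_x``
* dinucleotide preference        ``P_xy  = (n_xy / sum n_xy) / (P_x P_y)``
  (an odds ratio: 1 under compositional independence)
* synonymous codon usage         ``P_xyz = n_xyz / n_A``  (A = amino acid of xyz)
* amino-acid usage               ``P_A   = n_A / sum_A n_A``
* codon-pair score (Bias only)   ``CPS = n_pair / (n_AB P_c1 P_c2)``

Zero or missing values are floored at 1e-4 before the log2 transform, so a
positive entry marks an overrepresented trait and unobserved traits sit at
log2(1e-4).

The default ``sBias`` layout (version ``v1-137``) has 137 entries: genome-wide
nucleotide (4) and dinucleotide (16) preferences, synonymous codon usage (61),
amino-acid usage (20), plus nucleotide (4) and dinucleotide (16) preferences
recomputed over predicted coding regions and dinucleotide preferences at
codon-boundary ("bridge") positions (16).  The ``Bias`` layout appends the
3,904 codon-pair scores (pairs led by a stop codon excluded).

Coding regions come from a pluggable gene caller: an external Prodigal-style
executable, or a built-in ORF scanner that needs no external tool (all ORFs of
at least 300 nt on both strands, longest-first greedy non-overlapping
selection, with a longest-open-reading-frame fallback for fragments that
truncate every complete ORF).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NUCLEOTIDES",
    "DINUCLEOTIDES",
    "SENSE_CODONS",
    "STOP_CODONS",
    "AMINO_ACIDS",
    "CODON_PAIRS",
    "FEATURE_LAYOUT_VERSION",
    "UNOBSERVED_FLOOR",
    "Gene",
    "CodingAnnotation",
    "CompositionCounts",
    "predict_coding_regions",
    "count_compositions",
    "nucleotide_preference",
    "dinucleotide_preference",
    "codon_usage",
    "amino_acid_usage",
    "codon_pair_score",
    "normalize_and_log",
    "encode_traits",
    "feature_names",
    "GenomicTraitEncoder",
]

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = tuple(a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES)
SENSE_CODONS = tuple(c for c in _ALL_CODONS if c not in STOP_CODONS)
CODON_TO_AA = {c: str(Seq(c).translate()) for c in SENSE_CODONS}
AMINO_ACIDS = tuple(sorted(set(CODON_TO_AA.values())))
#: codon pairs for the Bias layout: first codon sense (61), second any (64)
CODON_PAIRS = tuple((c1, c2) for c1 in SENSE_CODONS for c2 in _ALL_CODONS)

FEATURE_LAYOUT_VERSION = "v1-137"
UNOBSERVED_FLOOR = 1e-4
MIN_ORF_LENGTH = 300


# ---------------------------------------------------------------------------
# gene calling


@dataclass(frozen=True)
class Gene:
    """One predicted gene: 1-based inclusive coordinates on the input genome."""

    start: int
    end: int
    strand: str  # "+" or "-"
    nt_seq: str  # in-frame nucleotide sequence (stop codon included if present)
    protein: str  # translation, stop excluded
    partial: bool = False


@dataclass
class CodingAnnotation:
    """Predicted genes of one genome (possibly empty)."""

    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def coding_sequences(self) -> list[str]:
        return [g.nt_seq for g in self.genes]


def _clean(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def _find_orfs(seq: str, strand: str, min_length: int) -> list[Gene]:
    """Complete ORFs (ATG..stop, inclusive) >= min_length on one strand."""
    n = len(seq)
    genes = []
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                length = i + 3 - start
                if length >= min_length:
                    orf = seq[start : i + 3]
                    protein = str(Seq(orf[:-3]).translate())
                    if strand == "+":
                        g_start, g_end = start + 1, i + 3
                    else:
                        g_start, g_end = n - (i + 3) + 1, n - start
                    genes.append(Gene(g_start, g_end, strand, orf, protein))
                start = None
    return genes


def _stop_free_runs(seq: str, strand: str, min_length: int) -> list[Gene]:
    """Partial-gene candidates: maximal stop-free in-frame runs >= min_length.

    Recovers the coding frame of fragments whose complete ORFs were truncated
    by the cut (no start and/or no stop codon inside the fragment).
    """
    n = len(seq)
    out: list[Gene] = []
    for frame in range(3):
        run_start = frame
        i = frame
        while i <= n - 3:
            if seq[i : i + 3] in STOP_CODONS:
                if i - run_start >= min_length:
                    out.append(_partial_gene(seq, run_start, i, strand, n))
                run_start = i + 3
            i += 3
        if i - run_start >= min_length:
            out.append(_partial_gene(seq, run_start, i, strand, n))
    return out


def _partial_gene(seq: str, start: int, end: int, strand: str, n: int) -> Gene:
    sub = seq[start:end]
    protein = str(Seq(sub).translate())
    if strand == "+":
        g_start, g_end = start + 1, end
    else:
        g_start, g_end = n - end + 1, n - start
    return Gene(g_start, g_end, strand, sub, protein, partial=True)


def _naive_orf_annotation(
    genome: str, min_length: int = MIN_ORF_LENGTH, allow_partial: bool = False
) -> CodingAnnotation:
    seq = _clean(genome)
    # ambiguous edges carry no gene signal and would shift frame bookkeeping
    core = seq.strip("".join(set(seq) - set(NUCLEOTIDES)) or "N")
    offset = seq.index(core) if core else 0
    seq = core
    rc = str(Seq(seq).reverse_complement())
    fwd = _find_orfs(seq, "+", min_length)
    rev = _find_orfs(rc, "-", min_length)
    candidates = fwd + rev
    if allow_partial:
        # fragments may truncate every complete ORF; stop-free runs recover
        # the coding frame in that case
        candidates += _filter_runs(_stop_free_runs(seq, "+", min_length), fwd)
        candidates += _filter_runs(_stop_free_runs(rc, "-", min_length), rev)
    chosen = _greedy_select(candidates)
    if offset:
        chosen = [
            Gene(g.start + offset, g.end + offset, g.strand, g.nt_seq, g.protein, g.partial)
            for g in chosen
        ]
    chosen.sort(key=lambda g: g.start)
    return CodingAnnotation(chosen)


def _filter_runs(runs: list[Gene], complete: list[Gene]) -> list[Gene]:
    """Drop runs that merely extend a complete ORF of the same strand upstream."""
    return [
        r
        for r in runs
        if not any(r.start <= o.start <= o.end <= r.end for o in complete)
    ]


def _greedy_select(candidates: list[Gene]) -> list[Gene]:
    """Longest-first greedy non-overlapping selection, deterministic tie-break."""
    candidates = sorted(
        candidates,
        key=lambda g: (-len(g.nt_seq), g.start, 0 if g.strand == "+" else 1),
    )
    chosen: list[Gene] = []
    for g in candidates:
        if all(g.end < h.start or g.start > h.end for h in chosen):
            chosen.append(g)
    return chosen


def _external_annotation(genome: str, executable: str) -> CodingAnnotation:
    """Delegate gene calling to a Prodigal-compatible executable."""
    exe = shutil.which(executable)
    if exe is None:
        raise FileNotFoundError(
            f"gene-caller executable {executable!r} not found on PATH; "
            "use the built-in ORF backend or configure the executable"
        )
    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "in.fa"
        genes_out = Path(tmp) / "genes.fna"
        fa.write_text(f">q\n{_clean(genome)}\n")
        subprocess.run(
            [exe, "-p", "meta", "-i", str(fa), "-d", str(genes_out), "-o", str(Path(tmp) / "o.gff"), "-f", "gff", "-q"],
            check=True,
            capture_output=True,
        )
        genes = []
        for header, seq in _iter_fasta(genes_out):
            # prodigal headers: >q_1 # start # end # strand # ...
            parts = header.split("#")
            start, end = int(parts[1]), int(parts[2])
            strand = "+" if int(parts[3]) > 0 else "-"
            seq = _clean(seq)
            seq = seq[: len(seq) - len(seq) % 3]
            protein = str(Seq(seq).translate()).rstrip("*")
            genes.append(Gene(start, end, strand, seq, protein))
        return CodingAnnotation(genes)


def _iter_fasta(path: Path):
    header, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        yield header, "".join(chunks)


def predict_coding_regions(
    genome: str,
    backend: str = "naive_orf",
    min_orf_length: int = MIN_ORF_LENGTH,
    executable: str = "prodigal",
    allow_partial: bool = False,
) -> CodingAnnotation:
    """Predict coding regions with the configured backend.

    ``naive_orf`` needs no external tool; ``external`` shells out to a
    Prodigal-compatible gene caller.  An input with no callable gene yields an
    empty annotation (codon-level traits then fall back to their unobserved
    floor).  With ``allow_partial`` the built-in backend falls back to the
    longest stop-free reading frame when no complete ORF exists, which keeps
    codon features informative on fragments that truncate every gene.
    """
    if len(genome) < 60:
        raise ValueError("genome shorter than 60 nt")
    if backend == "naive_orf":
        return _naive_orf_annotation(genome, min_orf_length, allow_partial)
    if backend == "external":
        return _external_annotation(genome, executable)
    raise ValueError(f"unknown gene-caller backend {backend!r}")


# ---------------------------------------------------------------------------
# composition counting


@dataclass
class CompositionCounts:
    """Raw occurrence counts underlying the trait equations.

    Nucleotide/dinucleotide counts span the full genome (overlapping windows,
    within each segment only); codon, amino-acid and pair counts span the
    concatenated predicted genes; coding/bridge variants are restricted to
    coding regions and codon-boundary positions.  Characters outside ACGT are
    skipped, never imputed.
    """

    nt: Counter = field(default_factory=Counter)
    dinuc: Counter = field(default_factory=Counter)
    coding_nt: Counter = field(default_factory=Counter)
    coding_dinuc: Counter = field(default_factory=Counter)
    bridge_dinuc: Counter = field(default_factory=Counter)
    codon: Counter = field(default_factory=Counter)
    aa: Counter = field(default_factory=Counter)
    codon_pair: Counter = field(default_factory=Counter)
    aa_pair: Counter = field(default_factory=Counter)


def _count_windows(seq: str, nt: Counter, dinuc: Counter) -> None:
    for ch in seq:
        if ch in NUCLEOTIDES:
            nt[ch] += 1
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair[0] in NUCLEOTIDES and pair[1] in NUCLEOTIDES:
            dinuc[pair] += 1


def count_compositions(
    genome: str | Sequence[str],
    annotation: CodingAnnotation | None = None,
) -> CompositionCounts:
    """Count all compositions of one genome (or the pooled segments of one virus)."""
    segments = [genome] if isinstance(genome, str) else list(genome)
    counts = CompositionCounts()
    for seg in segments:
        _count_windows(_clean(seg), counts.nt, counts.dinuc)
    if annotation is None:
        return counts
    for gene in annotation.genes:
        seq = _clean(gene.nt_seq)
        seq = seq[: len(seq) - len(seq) % 3]
        _count_windows(seq, counts.coding_nt, counts.coding_dinuc)
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        prev: str | None = None
        for j, codon in enumerate(codons):
            valid = codon in CODON_TO_AA
            if valid:
                counts.codon[codon] += 1
                counts.aa[CODON_TO_AA[codon]] += 1
            if j > 0:
                bridge = codons[j - 1][2] + codon[0]
                if bridge[0] in NUCLEOTIDES and bridge[1] in NUCLEOTIDES:
                    counts.bridge_dinuc[bridge] += 1
            if prev is not None and prev in CODON_TO_AA and codon in _ALL_CODONS and "N" not in codon:
                # pairs led by a stop codon are excluded by construction
                counts.codon_pair[(prev, codon)] += 1
                if valid:
                    counts.aa_pair[(CODON_TO_AA[prev], CODON_TO_AA[codon])] += 1
            prev = codon if len(codon) == 3 else None
    return counts


# ---------------------------------------------------------------------------
# trait equations (raw preferences; zeros mark unobserved events)


def nucleotide_preference(counts: CompositionCounts, context: str = "genome") -> dict[str, float]:
    """P_x = n_x / sum n_x over the genome or over coding regions."""
    src = counts.nt if context == "genome" else counts.coding_nt
    total = sum(src[x] for x in NUCLEOTIDES)
    if total == 0:
        return {x: 0.0 for x in NUCLEOTIDES}
    return {x: src[x] / total for x in NUCLEOTIDES}


def dinucleotide_preference(counts: CompositionCounts, context: str = "genome") -> dict[str, float]:
    """Odds ratio P_xy = (n_xy / sum n_xy) / (P_x P_y); unobserved pairs are 0.

    The marginal nucleotide frequencies come from the matching context
    (genome-wide for the genome context, coding-region frequencies for the
    coding and bridge contexts).
    """
    src = {"genome": counts.dinuc, "coding": counts.coding_dinuc, "bridge": counts.bridge_dinuc}[context]
    p_nt = nucleotide_preference(counts, "genome" if context == "genome" else "coding")
    total = sum(src[d] for d in DINUCLEOTIDES)
    out = {}
    for d in DINUCLEOTIDES:
        denom = p_nt[d[0]] * p_nt[d[1]]
        out[d] = (src[d] / total) / denom if total > 0 and denom > 0 and src[d] > 0 else 0.0
    return out


def codon_usage(counts: CompositionCounts) -> dict[str, float]:
    """Synonymous codon usage P_xyz = n_xyz / n_A for the encoded amino acid A."""
    out = {}
    for codon in SENSE_CODONS:
        n_a = counts.aa[CODON_TO_AA[codon]]
        out[codon] = counts.codon[codon] / n_a if n_a > 0 else 0.0
    return out


def amino_acid_usage(counts: CompositionCounts) -> dict[str, float]:
    """P_A = n_A / sum_A n_A over the concatenated predicted genes."""
    total = sum(counts.aa[a] for a in AMINO_ACIDS)
    if total == 0:
        return {a: 0.0 for a in AMINO_ACIDS}
    return {a: counts.aa[a] / total for a in AMINO_ACIDS}


def codon_pair_score(counts: CompositionCounts) -> dict[tuple[str, str], float]:
    """CPS(c1,c2) = n_{c1c2} / (n_AB * P_c1 * P_c2); pairs led by stops excluded."""
    usage = codon_usage(counts)
    out = {}
    for c1, c2 in CODON_PAIRS:
        n_pair = counts.codon_pair[(c1, c2)]
        if n_pair == 0 or c2 in STOP_CODONS:
            out[(c1, c2)] = 0.0
            continue
        n_ab = counts.aa_pair[(CODON_TO_AA[c1], CODON_TO_AA[c2])]
        denom = n_ab * usage[c1] * usage[c2]
        out[(c1, c2)] = n_pair / denom if denom > 0 else 0.0
    return out


def normalize_and_log(values: Mapping, floor: float = UNOBSERVED_FLOOR) -> dict:
    """Floor zeros/missing at ``floor`` and apply log2.

    Overrepresented traits come out positive, underrepresented negative, and
    unobserved traits equal log2(floor).
    """
    out = {}
    for k, v in values.items():
        if v < 0:
            raise ValueError(f"negative trait value for {k!r}: {v}")
        out[k] = float(np.log2(max(v, floor)))
    return out


# ---------------------------------------------------------------------------
# trait-vector assembly


def feature_names(feature_set: str = "sbias") -> list[str]:
    """Ordered feature names of the versioned trait layout."""
    names = [f"nt|{x}" for x in NUCLEOTIDES]
    names += [f"dinuc|{d}" for d in DINUCLEOTIDES]
    names += [f"codon|{c}" for c in SENSE_CODONS]
    names += [f"aa|{a}" for a in AMINO_ACIDS]
    names += [f"cnt|{x}" for x in NUCLEOTIDES]
    names += [f"cdinuc|{d}" for d in DINUCLEOTIDES]
    names += [f"bdinuc|{d}" for d in DINUCLEOTIDES]
    if feature_set == "bias":
        names += [f"cps|{c1},{c2}" for c1, c2 in CODON_PAIRS]
    elif feature_set != "sbias":
        raise ValueError(f"unknown feature set {feature_set!r}")
    return names


def encode_traits(
    genome: str | Sequence[str],
    annotation: CodingAnnotation | None = None,
    feature_set: str = "sbias",
    floor: float = UNOBSERVED_FLOOR,
) -> np.ndarray:
    """Encode one genome (or pooled segments) as its trait vector S.

    sBias yields 137 entries; Bias appends the 3,904 codon-pair scores.  When
    ``annotation`` is None the built-in ORF backend is applied to each segment.
    """
    segments = [genome] if isinstance(genome, str) else list(genome)
    if annotation is None:
        annotation = CodingAnnotation(
            [g for seg in segments for g in _naive_orf_annotation(seg).genes]
        )
    counts = count_compositions(segments, annotation)
    blocks = [
        nucleotide_preference(counts, "genome"),
        dinucleotide_preference(counts, "genome"),
        codon_usage(counts),
        amino_acid_usage(counts),
        nucleotide_preference(counts, "coding"),
        dinucleotide_preference(counts, "coding"),
        dinucleotide_preference(counts, "bridge"),
    ]
    if feature_set == "bias":
        blocks.append(codon_pair_score(counts))
    values: list[float] = []
    for block in blocks:
        logged = normalize_and_log(block, floor)
        values.extend(logged[k] for k in block)  # dicts preserve layout order
    return np.asarray(values, dtype=float)


class GenomicTraitEncoder(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer from genome sequences to trait vectors.

    Parameters
    ----------
    feature_set : {"sbias", "bias"}
        Without / with the codon-pair-score block.
    gene_caller : {"naive_orf", "external"}
        Coding-region backend; ``external`` requires a Prodigal-compatible
        executable on PATH.
    min_orf_length : int
        Minimum ORF length in nt for the built-in backend.
    """

    def __init__(
        self,
        feature_set: str = "sbias",
        gene_caller: str = "naive_orf",
        min_orf_length: int = MIN_ORF_LENGTH,
        gene_caller_executable: str = "prodigal",
        allow_partial: bool = True,
    ):
        self.feature_set = feature_set
        self.gene_caller = gene_caller
        self.min_orf_length = min_orf_length
        self.gene_caller_executable = gene_caller_executable
        self.allow_partial = allow_partial

    def fit(self, X: Iterable, y=None) -> "GenomicTraitEncoder":
        self.feature_names_ = feature_names(self.feature_set)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        """Encode an iterable of sequences (or per-virus segment lists)."""
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        return np.vstack([self.encode_one(item) for item in X])

    def encode_one(self, genome: str | Sequence[str]) -> np.ndarray:
        segments = [genome] if isinstance(genome, str) else list(genome)
        genes = []
        for seg in segments:
            ann = predict_coding_regions(
                seg,
                backend=self.gene_caller,
                min_orf_length=self.min_orf_length,
                executable=self.gene_caller_executable,
                allow_partial=self.allow_partial,
            )
            genes.extend(ann.genes)
        return encode_traits(segments, CodingAnnotation(genes), self.feature_set)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.feature_set), dtype=object)
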