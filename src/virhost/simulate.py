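"""Synthetic viral genomes with controllable host signal.

The generator emulates the two signals the predictor exploits: host-specific
genomic-trait usage (each host label gets a codon-usage profile whose
synonymous-codon concentration scales with ``bias_strength``, an amino-acid
composition, and a dinucleotide tilt applied to untranslated regions), and
genus-level sequence ancestry (each genus descends from one ancestor genome
by point substitutions, so same-genus sequences remain alignable and homology
features are informative).

At ``bias_strength`` 0 all synonymous codons are equiprobable and traits carry
no host signal; at 1 one codon per amino acid dominates (probability
>= 0.97), making host groups separable by traits alone.  Genomes are a 5' UTR,
one long ORF (at least 80% of the genome), and a 3' UTR.

Default configuration: one virus order with the five layer-1 host labels,
one family and five genera per label, 12 genomes per genus (60 genomes per
host label, 300 total, 25 genera — about the genus diversity a single virus
order contributes in curated reference sets), full-strength bias, 5% per-site
divergence within a genus (dereplicated reference sets retain comparable
within-genus diversity while staying easily alignable), genome lengths
1,200-2,400 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .taxonomy import LAYER1_LABELS, LAYER2_LABELS, MERGED_MAMMAL_LABEL, VirusRecord
from .traits import AMINO_ACIDS, CODON_TO_AA, NUCLEOTIDES, SENSE_CODONS

__all__ = ["HostProfile", "SimConfig", "make_host_profiles", "simulate_genome", "simulate_dataset"]

_CODONS_OF_AA: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _CODONS_OF_AA.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class HostProfile:
    """Trait-usage profile of one host label."""

    label: str
    codon_probs: dict[str, np.ndarray]  # amino acid -> probs over its codons
    aa_probs: np.ndarray  # over AMINO_ACIDS
    dinucleotide_tilt: float  # 0 = independent UTR composition
    preferred_next: dict[str, str]  # UTR Markov preference when tilted


def make_host_profiles(
    labels: Sequence[str], bias_strength: float, seed: int = 0
) -> list[HostProfile]:
    """One deterministic trait profile per host label.

    Profiles interpolate between uniform synonymous-codon usage (strength 0)
    and near-deterministic preferred-codon choice (strength 1).
    """
    if not 0 <= bias_strength <= 1:
        raise ValueError("bias_strength must lie in [0, 1]")
    rng = np.random.RandomState(seed)
    profiles = []
    # Ser and Leu keep fixed preferred codons whose reverse complements are
    # stop codons (rc(TCA)=TGA, rc(TTA)=TAA): real coding sequences carry
    # stops in their reverse-complement frames at regular density, and
    # without this anchor a fully biased codon stream can leave the reverse
    # strand free of stops, creating long spurious ORFs no real genome shows
    fixed_preferred = {"S": "TCA", "L": "TTA"}
    for label in labels:
        codon_probs = {}
        for aa, codons in _CODONS_OF_AA.items():
            k = len(codons)
            uniform = np.full(k, 1.0 / k)
            if aa in fixed_preferred:
                preferred = codons.index(fixed_preferred[aa])
            else:
                preferred = rng.randint(k)
            point = np.zeros(k)
            point[preferred] = 1.0
            codon_probs[aa] = (1 - bias_strength) * uniform + bias_strength * point
        uniform_aa = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        tilted_aa = rng.dirichlet(np.full(len(AMINO_ACIDS), 5.0))
        aa_probs = (1 - bias_strength) * uniform_aa + bias_strength * tilted_aa
        preferred_next = {x: NUCLEOTIDES[rng.randint(4)] for x in NUCLEOTIDES}
        profiles.append(
            HostProfile(
                label=label,
                codon_probs=codon_probs,
                aa_probs=aa_probs,
                dinucleotide_tilt=bias_strength,
                preferred_next=preferred_next,
            )
        )
    return profiles


def _utr(profile: HostProfile, length: int, rng: np.random.RandomState) -> str:
    if length <= 0:
        return ""
    # mild first-order tilt: strong enough to bias dinucleotide usage, weak
    # enough that UTRs stay far from homopolymers (which would make overall
    # composition hypersensitive to where a fragment cut lands)
    tilt = profile.dinucleotide_tilt
    out = [NUCLEOTIDES[rng.randint(4)]]
    for _ in range(length - 1):
        if tilt > 0 and rng.random_sample() < 0.25 + 0.2 * tilt:
            out.append(profile.preferred_next[out[-1]])
        else:
            out.append(NUCLEOTIDES[rng.randint(4)])
    return "".join(out)


def simulate_genome(
    profile: HostProfile,
    length: int,
    seed: int | np.random.RandomState = 0,
    aa_jitter: float = 150.0,
) -> tuple[str, tuple[int, int]]:
    """Simulate one genome; returns (sequence, (orf_start, orf_end) 1-based).

    Layout: 5' UTR + ATG + sampled codons + TAA + 3' UTR; the ORF covers at
    least 80% of the genome (its exact fraction varies per genome) and the
    output length is exact.  ``aa_jitter`` is the Dirichlet concentration of
    the per-genome amino-acid composition around the host profile: real
    genomes of one host class are not compositional clones, and this
    within-class variance is what keeps classifiers from memorising razor-thin
    composition thresholds.
    """
    if length < 600:
        raise ValueError("genome length must be >= 600 nt")
    rng = seed if isinstance(seed, np.random.RandomState) else np.random.RandomState(seed)
    orf_frac = rng.uniform(0.82, 0.94)
    orf_len = 3 * int(np.floor(orf_frac * length / 3))
    n_codons = orf_len // 3 - 2  # minus start and stop
    genome_aa = rng.dirichlet(profile.aa_probs * aa_jitter + 0.2)
    aa_idx = rng.choice(len(AMINO_ACIDS), size=n_codons, p=genome_aa)
    codons = []
    for i in aa_idx:
        aa = AMINO_ACIDS[i]
        options = _CODONS_OF_AA[aa]
        codons.append(options[rng.choice(len(options), p=profile.codon_probs[aa])])
    orf = "ATG" + "".join(codons) + "TAA"
    utr_total = length - orf_len
    utr5 = utr_total // 2
    seq = _utr(profile, utr5, rng) + orf + _utr(profile, utr_total - utr5, rng)
    assert len(seq) == length
    return seq, (utr5 + 1, utr5 + orf_len)


def _mutate(seq: str, rate: float, rng: np.random.RandomState) -> str:
    """Point substitutions at the given per-site rate (no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random_sample(len(arr)) < rate)
    for i in hits:
        current = arr[i].decode()
        choices = [x for x in NUCLEOTIDES if x != current]
        arr[i] = choices[rng.randint(3)].encode()
    return arr.tobytes().decode()


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-dataset configuration (defaults are the study conditions)."""

    n_orders: int = 1
    families_per_order: int = 5
    genera_per_family: int = 5
    genomes_per_genus: int = 12
    host_labels: tuple[str, ...] = LAYER1_LABELS
    bias_strength: float = 1.0
    mutation_rate: float = 0.05
    length_range: tuple[int, int] = (1200, 2400)
    seed: int = 0
    #: "by_family": families map round-robin onto host labels and genera
    #: inherit their family's label; "planted": every genus gets the first
    #: label except the last ``planted_case1_genera``, which get the second
    label_assignment: str = "by_family"
    planted_case1_genera: int = 0

    def __post_init__(self) -> None:
        if min(self.n_orders, self.families_per_order, self.genera_per_family, self.genomes_per_genus) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.mutation_rate <= 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5]")


def simulate_dataset(config: SimConfig) -> tuple[list[VirusRecord], dict[str, str]]:
    """Simulate a full reference set: records (with taxonomy + host labels) and sequences.

    Every genus draws one ancestor genome from its host profile and derives
    its members by point substitutions at ``mutation_rate``, so same-genus
    sequences stay alignable.
    """
    rng = np.random.RandomState(config.seed)
    profiles = {
        p.label: p
        for p in make_host_profiles(config.host_labels, config.bias_strength, config.seed)
    }
    records: list[VirusRecord] = []
    sequences: dict[str, str] = {}
    for o in range(config.n_orders):
        order = f"SimOrder{o + 1}"
        genus_no = 0
        for f in range(config.families_per_order):
            family = f"{order}F{f + 1}"
            family_label = config.host_labels[f % len(config.host_labels)]
            for g in range(config.genera_per_family):
                genus_no += 1
                genus = f"{family}G{g + 1}"
                if config.label_assignment == "by_family":
                    label = family_label
                elif config.label_assignment == "planted":
                    total_genera = config.families_per_order * config.genera_per_family
                    planted = genus_no > total_genera - config.planted_case1_genera
                    label = config.host_labels[1 if planted else 0]
                else:
                    raise ValueError(f"unknown label_assignment {config.label_assignment!r}")
                length = int(rng.randint(config.length_range[0], config.length_range[1] + 1))
                ancestor, _ = simulate_genome(profiles[label], length, rng)
                for i in range(config.genomes_per_genus):
                    rid = f"{genus}n{i + 1:03d}"
                    seq = _mutate(ancestor, config.mutation_rate, rng)
                    sequences[rid] = seq
                    records.append(_make_record(rid, order, family, genus, label, len(seq)))
    return records, sequences


def _make_record(
    rid: str, order: str, family: str, genus: str, label: str, length: int
) -> VirusRecord:
    if label in LAYER2_LABELS or label == MERGED_MAMMAL_LABEL:
        layer1, layer2 = "Chordata", label
    else:
        layer1, layer2 = label, None
    return VirusRecord(
        id=rid,
        order=order,
        family=family,
        genus=genus,
        layer1_host=layer1,
        layer2_host=layer2,
        sequence_length=length,
        all_layer1_hosts=(layer1,),
    )
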