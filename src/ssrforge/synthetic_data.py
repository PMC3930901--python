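"""Seeded synthetic inputs with exact known truth.

Three generators feed the test pyramid: genomes with planted SSR tracts
whose background is guaranteed free of qualifying repeats, mutated
alternate genotypes with per-locus repeat-count deltas and flank SNPs, and
genotype matrices drawn from known group-level allele frequencies.  All
generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasiblePlacementError
from .genotype_stats import GenotypeMatrix
from .ssr_scan import (
    MOTIF_CLASSES,
    CLASS_BY_UNIT_LENGTH,
    ScanConfig,
    SSRLocus,
    canonical_family,
    scan_sequence,
)

__all__ = [
    "PlantSpec",
    "GenomeTruth",
    "generate_genome",
    "derive_genotype",
    "simulate_genotype_matrix",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """One SSR tract to plant: ``position`` is the 1-based tract start."""

    seq_id: str
    position: int
    motif: str
    repeat_count: int

    @property
    def tract(self) -> str:
        return self.motif * self.repeat_count

    @property
    def end(self) -> int:
        return self.position + len(self.tract) - 1


@dataclass
class GenomeTruth:
    """Planted loci plus, after :func:`derive_genotype`, per-assembly
    repeat-count deltas keyed by locus id."""

    loci: list[SSRLocus]
    deltas: dict[str, dict[str, int]] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_to_locus(spec: PlantSpec) -> SSRLocus:
    k = len(spec.motif)
    cls = CLASS_BY_UNIT_LENGTH[k]
    return SSRLocus(
        locus_id=f"{spec.seq_id}:{spec.position}:{cls}",
        seq_id=spec.seq_id,
        start=spec.position,
        end=spec.end,
        motif=spec.motif,
        family=canonical_family(spec.motif),
        motif_class=cls,
        repeat_count=spec.repeat_count,
        tract_length=k * spec.repeat_count,
    )


def generate_genome(
    n_seqs: int,
    length: int,
    plant_specs: Sequence[PlantSpec],
    seed: int,
    config: ScanConfig | None = None,
    min_separation: int = 200,
    max_rounds: int = 100,
) -> tuple[dict[str, str], GenomeTruth]:
    """Random genome with exactly the planted SSRs and nothing else.

    Sequences are named ``seq1..seqN``.  Background windows are re-sampled
    until a scan under ``config`` recovers exactly the planted loci, so the
    truth table is exact by construction rather than by masking.
    """
    if config is None:
        config = ScanConfig()
    rng = np.random.default_rng(seed)
    seq_ids = [f"seq{i + 1}" for i in range(n_seqs)]
    by_seq: dict[str, list[PlantSpec]] = {s: [] for s in seq_ids}
    for spec in plant_specs:
        if spec.seq_id not in by_seq:
            raise InfeasiblePlacementError(f"unknown sequence {spec.seq_id!r}")
        if spec.position < 2 or spec.end > length - 1:
            raise InfeasiblePlacementError(
                f"plant at {spec.seq_id}:{spec.position} does not fit inside 2..{length - 1}"
            )
        by_seq[spec.seq_id].append(spec)
    for specs in by_seq.values():
        specs.sort(key=lambda s: s.position)
        for a, b in zip(specs, specs[1:]):
            if b.position - a.end - 1 < min_separation:
                raise InfeasiblePlacementError(
                    f"plants {a.seq_id}:{a.position} and {b.position} closer than {min_separation} bp"
                )

    genome: dict[str, str] = {}
    truth_loci: list[SSRLocus] = []
    for seq_id in seq_ids:
        specs = by_seq[seq_id]
        expected = {
            (s.position, s.end, canonical_family(s.motif), s.repeat_count) for s in specs
        }
        planted = {(s.position, s.end) for s in specs}
        seq = list(_random_seq(rng, length))
        for s in specs:
            seq[s.position - 1 : s.end] = list(s.tract)
        for _ in range(max_rounds):
            _break_extensions(seq, specs, rng)
            found = scan_sequence(seq_id, "".join(seq), config)
            bad = [
                l for l in found
                if (l.start, l.end, l.family, l.repeat_count) not in expected
            ]
            if not bad and len(found) == len(specs):
                break
            for l in bad:
                lo, hi = l.start - 1, l.end
                window = _random_seq(rng, hi - lo)
                for off, c in enumerate(window):
                    p = lo + off
                    # never touch a planted tract
                    if any(ps - 1 <= p < pe for ps, pe in planted):
                        continue
                    seq[p] = c
        else:
            raise InfeasiblePlacementError("could not generate a repeat-free background")
        genome[seq_id] = "".join(seq)
        truth_loci.extend(_plant_to_locus(s) for s in specs)
    return genome, GenomeTruth(loci=truth_loci)


def _break_extensions(seq: list[str], specs: Sequence[PlantSpec], rng: np.random.Generator) -> None:
    """Force the bases adjacent to each planted tract to break the repeat
    phase, so the scanner reports exactly the planted coordinates."""
    for s in specs:
        k = len(s.motif)
        left = s.position - 2  # 0-based index of base before tract
        if left >= 0 and seq[left] == s.motif[-1]:
            choices = [b for b in "ACGT" if b != s.motif[-1]]
            seq[left] = choices[int(rng.integers(0, len(choices)))]
        right = s.end  # 0-based index of base after tract
        if right < len(seq) and seq[right] == s.motif[0]:
            choices = [b for b in "ACGT" if b != s.motif[0]]
            seq[right] = choices[int(rng.integers(0, len(choices)))]


def derive_genotype(
    genome: Mapping[str, str],
    truth: GenomeTruth,
    deltas: Mapping[str, int],
    seed: int,
    assembly_name: str = "alt",
    flank_snp_rate: float = 0.0,
    anchor_window: int = 50,
    snps_in_anchors: bool = False,
) -> tuple[dict[str, str], GenomeTruth]:
    """Alternate genotype: each planted tract expanded/contracted by its
    repeat-count delta, flank substitutions at ``flank_snp_rate``.

    SNPs never fall inside the tracts nor (unless ``snps_in_anchors``,
    a stress mode for anchoring failure tests) within ``anchor_window``
    bases of a tract edge.  The delta map is keyed by locus id; missing
    loci keep delta 0.  The updated truth records every delta under
    ``assembly_name``.
    """
    rng = np.random.default_rng(seed)
    loci_by_seq: dict[str, list[SSRLocus]] = {}
    for locus in truth.loci:
        loci_by_seq.setdefault(locus.seq_id, []).append(locus)
    for loci in loci_by_seq.values():
        loci.sort(key=lambda l: l.start)

    recorded: dict[str, int] = {}
    alt: dict[str, str] = {}
    for seq_id, seq in genome.items():
        loci = loci_by_seq.get(seq_id, [])
        pieces: list[str] = []
        cursor = 0  # 0-based
        for locus in loci:
            delta = int(deltas.get(locus.locus_id, 0))
            new_count = locus.repeat_count + delta
            if new_count < 1:
                raise ValueError(f"delta {delta} leaves {locus.locus_id} with < 1 repeat")
            recorded[locus.locus_id] = delta
            between = list(seq[cursor : locus.start - 1])
            _mutate_flank(
                between,
                rng,
                flank_snp_rate,
                protect_tail=0 if snps_in_anchors else anchor_window,
                protect_head=0 if snps_in_anchors or cursor == 0 else anchor_window,
                invert=snps_in_anchors,
                anchor_window=anchor_window,
            )
            pieces.append("".join(between))
            pieces.append(locus.motif * new_count)
            cursor = locus.end
        tail = list(seq[cursor:])
        _mutate_flank(
            tail,
            rng,
            flank_snp_rate,
            protect_tail=0,
            protect_head=0 if snps_in_anchors or not loci else anchor_window,
            invert=snps_in_anchors,
            anchor_window=anchor_window,
        )
        pieces.append("".join(tail))
        alt[seq_id] = "".join(pieces)

    new_truth = GenomeTruth(loci=list(truth.loci), deltas=dict(truth.deltas))
    new_truth.deltas[assembly_name] = recorded
    return alt, new_truth


def _mutate_flank(
    segment: list[str],
    rng: np.random.Generator,
    rate: float,
    protect_tail: int,
    protect_head: int,
    invert: bool,
    anchor_window: int,
) -> None:
    """Substitute bases in-place at ``rate``.

    ``protect_head``/``protect_tail`` exclude the bases nearest the
    adjacent tracts (the anchor windows).  With ``invert`` the SNPs are
    instead confined to those windows (stress mode).
    """
    if rate <= 0 or not segment:
        return
    n = len(segment)
    for i in range(n):
        in_anchor = i < anchor_window or i >= n - anchor_window
        if invert:
            if not in_anchor:
                continue
        else:
            if i >= n - protect_tail and protect_tail:
                continue
            if i < protect_head and protect_head:
                continue
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != segment[i]]
            segment[i] = choices[int(rng.integers(0, len(choices)))]


def simulate_genotype_matrix(
    n_markers: int,
    groups: Mapping[str, int],
    divergence: float,
    allele_counts: Sequence[int] = (2, 3, 4, 5, 6),
    concentration: float = 1.0,
    missing_rate: float | Mapping[str, float] = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, dict[str, dict[str, dict[int, float]]]]:
    """Genotype matrix sampled from known group-level allele frequencies.

    Per marker: an allele count k is drawn from ``allele_counts``, a shared
    base profile from Dirichlet(concentration), and each group's profile is
    ``(1 - divergence) * base + divergence * own`` with its own independent
    Dirichlet draw — one knob from identical groups (0) to independent
    profiles (1).  Calls are homozygous (selfing panel); ``missing_rate``
    may be a single rate or a per-group mapping.

    Returns the matrix and true frequencies ``{marker: {group: profile}}``.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    for size in groups.values():
        if size < 1:
            raise ValueError("group sizes must be >= 1")
    rng = np.random.default_rng(seed)
    group_names = list(groups)
    accessions = [f"{g}_{i + 1}" for g in group_names for i in range(groups[g])]
    group_of = {f"{g}_{i + 1}": g for g in group_names for i in range(groups[g])}
    markers = [f"M{m + 1:04d}" for m in range(n_markers)]

    def rate_for(group: str) -> float:
        if isinstance(missing_rate, Mapping):
            return float(missing_rate.get(group, 0.0))
        return float(missing_rate)

    calls: dict[tuple[str, str], tuple[int, ...] | None] = {}
    true_freqs: dict[str, dict[str, dict[int, float]]] = {}
    for marker in markers:
        k = int(allele_counts[int(rng.integers(0, len(allele_counts)))])
        sizes = [100 + 2 * a for a in range(k)]
        base = rng.dirichlet([concentration] * k)
        true_freqs[marker] = {}
        profiles: dict[str, np.ndarray] = {}
        for g in group_names:
            own = rng.dirichlet([concentration] * k)
            prof = (1.0 - divergence) * base + divergence * own
            prof = prof / prof.sum()
            profiles[g] = prof
            true_freqs[marker][g] = dict(zip(sizes, prof.tolist()))
        for acc in accessions:
            g = group_of[acc]
            if rng.random() < rate_for(g):
                calls[(marker, acc)] = None
            else:
                allele = sizes[int(rng.choice(len(sizes), p=profiles[g]))]
                calls[(marker, acc)] = (allele,)

    matrix = GenotypeMatrix(
        markers=markers, accessions=accessions, groups=dict(group_of), calls=calls
    )
    return matrix, true_freqs
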