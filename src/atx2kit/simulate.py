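"""Seeded generators of synthetic inputs with recorded ground truth.

Each generator emulates one class of input the analysis consumes —
IDR-like protein backgrounds with planted homopolymer tracts, motifs and
tandem arrays; domain-annotation cohorts with a stated chimeric fraction;
BLAST hit tables with planted E-value strata — and returns the generated
records together with a truth table of the planted features, so every
detector can be tested for exact recovery without any download.

Determinism: every generator is a pure function of its spec (seed
included). Each generator draws from its own stream, derived from the
master seed and a fixed per-generator key, so adding a generator never
perturbs the output of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .io import AMINO_ACIDS, BlastHit, DomainAnnotation, SequenceRecord
from .repeats import LEFT_TERMINUS, RIGHT_TERMINUS, RepeatCall
from .motifs import ConsensusModel
from .tandem import TandemDuplication

_STREAM_KEYS = {
    "repeat": 1,
    "motif": 2,
    "tandem": 3,
    "architecture": 4,
    "blast": 5,
}


class SimSpecError(ValueError):
    """Raised when a simulation spec is internally inconsistent."""


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM_KEYS[stream]]))


def _background(
    rng: np.random.Generator,
    length: int,
    frequencies: Optional[Mapping[str, float]] = None,
) -> str:
    """IDR-like background; uniform over the 20 amino acids by default."""
    if frequencies is None:
        letters = AMINO_ACIDS
        probs = np.full(len(letters), 1 / len(letters))
    else:
        letters = sorted(frequencies)
        probs = np.array([frequencies[a] for a in letters], dtype=float)
        probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


# ---------------------------------------------------------------------------
# repeat cohorts


@dataclass(frozen=True)
class PlantedRepeat:
    """One homopolymer tract to plant.

    ``interruptions`` lists (after_n_targets, run): the run string is
    inserted after that many target residues. Flanks are single residues
    placed immediately outside the tract.
    """

    residue: str = "Q"
    total: int = 23
    interruptions: Tuple[Tuple[int, str], ...] = ()
    left_flank: str = "P"
    right_flank: str = "P"

    def tract(self) -> str:
        pieces = []
        prev = 0
        for after, run in sorted(self.interruptions):
            if not (0 < after < self.total):
                raise SimSpecError("interruption must fall strictly inside the tract")
            if self.residue in run:
                raise SimSpecError("interruption run must not contain the target residue")
            pieces.append(self.residue * (after - prev))
            pieces.append(run)
            prev = after
        pieces.append(self.residue * (self.total - prev))
        if self.residue in (self.left_flank, self.right_flank):
            raise SimSpecError("flank must differ from the target residue")
        return "".join(pieces)


@dataclass(frozen=True)
class RepeatCohortSpec:
    seed: int = 0
    n_sequences: int = 10
    length: int = 200
    planted: Tuple[Optional[PlantedRepeat], ...] = ()
    background_frequencies: Optional[Tuple[Tuple[str, float], ...]] = None
    guard: int = 3  # target-free band enforced around the tract


def gen_repeat_cohort(
    spec: RepeatCohortSpec,
) -> Tuple[List[SequenceRecord], List[RepeatCall]]:
    """Sequences with at most one planted tract each, plus the truth calls.

    ``spec.planted`` gives one entry per sequence (None = background
    only); missing entries default to None. The tract (with its flanks)
    is placed at a uniformly random valid offset; a guard band around it
    is cleared of the target residue so the planted call is exactly the
    maximal call a detector with ``max_gap <= guard`` can make there.
    """
    rng = _rng(spec.seed, "repeat")
    freqs = dict(spec.background_frequencies) if spec.background_frequencies else None
    records: List[SequenceRecord] = []
    truth: List[RepeatCall] = []
    planted = list(spec.planted) + [None] * (spec.n_sequences - len(spec.planted))
    for i in range(spec.n_sequences):
        seq_id = f"sim{i:03d}"
        bg = _background(rng, spec.length, freqs)
        plant = planted[i]
        if plant is None:
            records.append(SequenceRecord(seq_id, bg, "protein"))
            continue
        tract = plant.tract()
        insert = plant.left_flank + tract + plant.right_flank
        if len(insert) + 2 * spec.guard > spec.length:
            raise SimSpecError(
                f"planted tract ({len(insert)} aa + guards) exceeds sequence length {spec.length}"
            )
        offset = int(rng.integers(spec.guard, spec.length - len(insert) - spec.guard + 1))
        seq = list(bg)
        seq[offset : offset + len(insert)] = insert
        # clear the guard bands of the target residue so the planted call
        # is maximal and cannot merge with background runs
        repl = "L" if plant.residue != "L" else "V"
        for j in list(range(offset - spec.guard, offset)) + list(
            range(offset + len(insert), offset + len(insert) + spec.guard)
        ):
            if seq[j] == plant.residue:
                seq[j] = repl
        records.append(SequenceRecord(seq_id, "".join(seq), "protein"))
        tract_start = offset + 2  # 1-based, after the left flank
        inter = []
        for after, run in sorted(plant.interruptions):
            pos = tract_start + after + sum(len(r) for _, r in inter)
            inter.append((pos, run))
        truth.append(
            RepeatCall(
                sequence_id=seq_id,
                target_residue=plant.residue,
                start=tract_start,
                end=tract_start + len(tract) - 1,
                count_target=plant.total,
                interruptions=tuple(inter),
                left_flank=plant.left_flank,
                right_flank=plant.right_flank,
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# motif cohorts


@dataclass(frozen=True)
class MotifCohortSpec:
    seed: int = 0
    n_sequences: int = 5
    length: int = 300
    n_lowercase_mutations: int = 0


def gen_motif_cohort(
    spec: MotifCohortSpec, model: ConsensusModel
) -> Tuple[List[SequenceRecord], List[Tuple[str, int, int]]]:
    """Plant one motif instance per sequence, mutated at lowercase positions.

    Returns the records and a truth table of (sequence_id, 1-based start,
    n_mutations). The planted window is the pattern's own letters
    (uppercased) with ``n_lowercase_mutations`` weakly conserved positions
    substituted; the rest of the sequence is background with the planted
    window's region excluded from resampling.
    """
    rng = _rng(spec.seed, "motif")
    pattern = model.pattern
    low_positions = [i for i, c in enumerate(pattern) if c.islower()]
    if spec.n_lowercase_mutations > len(low_positions):
        raise SimSpecError("more mutations requested than lowercase positions")
    records, truth = [], []
    for i in range(spec.n_sequences):
        seq_id = f"mot{i:03d}"
        bg = _background(rng, spec.length)
        window = list(pattern.upper())
        mut_at = rng.choice(low_positions, size=spec.n_lowercase_mutations, replace=False)
        for j in sorted(int(x) for x in mut_at):
            current = window[j]
            choices = [a for a in AMINO_ACIDS if a != current]
            window[j] = str(rng.choice(choices))
        offset = int(rng.integers(0, spec.length - len(pattern) + 1))
        seq = bg[:offset] + "".join(window) + bg[offset + len(pattern):]
        records.append(SequenceRecord(seq_id, seq, "protein"))
        truth.append((seq_id, offset + 1, spec.n_lowercase_mutations))
    return records, truth


# ---------------------------------------------------------------------------
# tandem cohorts


@dataclass(frozen=True)
class TandemCohortSpec:
    seed: int = 0
    n_sequences: int = 5
    length: int = 150
    unit: str = "PGCPRPA"
    copies: int = 2


def gen_tandem_cohort(
    spec: TandemCohortSpec,
) -> Tuple[List[SequenceRecord], List[TandemDuplication]]:
    """Plant one tandem array per sequence; truth rows use the planted phase.

    The background characters adjacent to the array are constrained so the
    periodic run neither extends nor gains a phase shift: the character
    before the array must differ from the unit's last character and the
    character after it from the unit's first.
    """
    rng = _rng(spec.seed, "tandem")
    unit = spec.unit.upper()
    if spec.copies < 2:
        raise SimSpecError("copies must be >= 2")
    array = unit * spec.copies
    records, truth = [], []
    for i in range(spec.n_sequences):
        seq_id = f"tan{i:03d}"
        if len(array) + 2 > spec.length:
            raise SimSpecError("planted array exceeds sequence length")
        bg = _background(rng, spec.length)
        offset = int(rng.integers(1, spec.length - len(array)))
        seq = list(bg)
        seq[offset : offset + len(array)] = array
        if seq[offset - 1] == unit[-1]:
            seq[offset - 1] = "W" if unit[-1] != "W" else "Y"
        after = offset + len(array)
        if after < len(seq) and seq[after] == unit[0]:
            seq[after] = "W" if unit[0] != "W" else "Y"
        records.append(SequenceRecord(seq_id, "".join(seq), "protein"))
        truth.append(
            TandemDuplication(
                sequence_id=seq_id, unit=unit, start=offset + 1, copies=spec.copies
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# architecture cohorts


@dataclass(frozen=True)
class ArchitectureCohortSpec:
    seed: int = 0
    n_proteins: int = 100
    chimera_fraction: float = 0.05
    chimera_categories: Tuple[Tuple[str, float], ...] = (
        ("rRNA processing", 0.6),
        ("membrane stress resistance", 0.3),
        ("other", 0.1),
    )
    background_categories: Tuple[Tuple[str, int], ...] = (
        ("rRNA processing", 10),
        ("membrane stress resistance", 10),
        ("other", 80),
    )
    long_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.chimera_fraction <= 1:
            raise SimSpecError("chimera fraction must lie in [0, 1]")


def gen_architecture_cohort(
    spec: ArchitectureCohortSpec,
) -> Tuple[Dict[str, int], List[DomainAnnotation], Dict[str, str], Dict[str, int], Dict[str, str]]:
    """Cohort of protein layouts with a planted chimeric fraction.

    Returns (lengths, domain annotations, extra-label -> category map,
    background category counts, truth verdicts). Non-chimeric proteins
    are canonical (full core) or partial (PAM2 dropped) at a fixed 4:1
    ratio; chimeric proteins get one extra domain on a random side with a
    category drawn from ``chimera_categories``.
    """
    rng = _rng(spec.seed, "architecture")
    lengths: Dict[str, int] = {}
    domains: List[DomainAnnotation] = []
    category_map: Dict[str, str] = {}
    truth: Dict[str, str] = {}
    cats, cat_probs = zip(*spec.chimera_categories)
    cat_probs = np.array(cat_probs) / np.sum(cat_probs)
    extra_counter = 0
    for i in range(spec.n_proteins):
        pid = f"prot{i:03d}"
        length = 900 if rng.random() >= spec.long_fraction else 1200
        lengths[pid] = length
        is_chimera = rng.random() < spec.chimera_fraction
        is_partial = (not is_chimera) and rng.random() < 0.2
        core = [("LSm", 300, 377), ("LSmAD", 430, 500)]
        if not is_partial:
            core.append(("PAM2", 700, 713))
        for label, s, e in core:
            domains.append(DomainAnnotation(pid, label, s, e))
        if is_chimera:
            extra_counter += 1
            label = f"XDOM{extra_counter:03d}"
            category_map[label] = str(rng.choice(cats, p=cat_probs))
            side = "N" if rng.random() < 0.5 else "C"
            if side == "N":
                domains.append(DomainAnnotation(pid, label, 10, 200))
                truth[pid] = "chimeric_N"
            else:
                domains.append(DomainAnnotation(pid, label, 750, min(880, length - 10)))
                truth[pid] = "chimeric_C"
        else:
            truth[pid] = "partial" if is_partial else "canonical"
    background = dict(spec.background_categories)
    return lengths, domains, category_map, background, truth


# ---------------------------------------------------------------------------
# BLAST strata


@dataclass(frozen=True)
class BlastStratum:
    tier: str  # tier1 | tier2 | tier3 | rejected
    evalue_range: Tuple[float, float]
    count: int


# default strata consistent with the default TierConfig thresholds
DEFAULT_STRATA = (
    BlastStratum("tier1", (1e-40, 1e-11), 10),
    BlastStratum("tier2", (1e-40, 1e-11), 10),
    BlastStratum("tier3", (1e-9, 4e-7), 5),
    BlastStratum("rejected", (1e-5, 1e-2), 5),
)


def gen_blast_strata(
    strata: Sequence[BlastStratum] = DEFAULT_STRATA,
    seed: int = 0,
    strict_threshold: float = 1e-10,
    loose_threshold: float = 5e-7,
) -> Tuple[List[BlastHit], Dict[str, str]]:
    """A hit table with planted E-value strata, plus truth tiers.

    Anchor (LSmAD) E-values are drawn log-uniformly inside each stratum's
    range; tier1 subjects additionally get an LSm supporting hit. A
    stratum whose range straddles the relevant threshold is rejected as
    inconsistent.
    """
    rng = _rng(seed, "blast")
    hits: List[BlastHit] = []
    truth: Dict[str, str] = {}
    n = 0
    for stratum in strata:
        lo, hi = stratum.evalue_range
        if not 0 < lo <= hi:
            raise SimSpecError(f"bad evalue range {stratum.evalue_range}")
        if stratum.tier in ("tier1", "tier2") and hi > strict_threshold:
            raise SimSpecError(f"{stratum.tier} range {stratum.evalue_range} crosses strict threshold")
        if stratum.tier == "tier3" and (lo <= strict_threshold or hi > loose_threshold):
            raise SimSpecError(f"tier3 range {stratum.evalue_range} crosses a threshold")
        if stratum.tier == "rejected" and lo <= loose_threshold:
            raise SimSpecError(f"rejected range {stratum.evalue_range} crosses loose threshold")
        for _ in range(stratum.count):
            n += 1
            subject = f"subj{n:03d}"
            evalue = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            hits.append(
                BlastHit(
                    query_id="LSmAD",
                    subject_id=subject,
                    percent_identity=float(np.round(rng.uniform(30, 95), 1)),
                    align_length=70,
                    mismatches=10,
                    gap_opens=0,
                    query_start=1,
                    query_end=70,
                    subject_start=100,
                    subject_end=169,
                    evalue=evalue,
                    bitscore=float(np.round(rng.uniform(40, 200), 1)),
                )
            )
            if stratum.tier == "tier1":
                hits.append(
                    BlastHit(
                        query_id="LSm",
                        subject_id=subject,
                        percent_identity=float(np.round(rng.uniform(30, 95), 1)),
                        align_length=78,
                        mismatches=20,
                        gap_opens=1,
                        query_start=1,
                        query_end=78,
                        subject_start=10,
                        subject_end=87,
                        evalue=float(np.exp(rng.uniform(np.log(1e-8), np.log(1e-3)))),
                        bitscore=float(np.round(rng.uniform(30, 100), 1)),
                    )
                )
            truth[subject] = stratum.tier
    return hits, truth
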