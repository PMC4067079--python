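"""Synthetic genomes with planted rolling-circle elements and full ground truth.

Element copies are inserted between the two Ts of a TT dinucleotide (the
observed target preference) carrying 2-5 extra terminal Ts of their own on
each end; canonical-Helitron copies are inserted at an A|T junction instead.
Optionally the pre-insertion locus is first duplicated elsewhere in the
genome, creating the paralogous empty sites the boundary validation relies
on.  A fixed seed gives byte-identical output; each element copy draws from
its own child RNG stream so adding copies never perturbs earlier ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .seq_io import GenomicInterval, SequenceRecord, reverse_complement

__all__ = [
    "ElementSpec",
    "ElementTruth",
    "Insertion",
    "EmptySiteTruth",
    "SyntheticTruth",
    "generate_background",
    "make_element",
    "plant_insertions",
    "make_deletion_derivative",
]

_BASES = np.array(list("ACGT"))
_NON_T = np.array(list("ACG"))

# back-translation table (one codon per residue, no stops)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_REP_MOTIF_AA = "VELQARGSPHIH"


@dataclass
class ElementSpec:
    """Design parameters for one master element."""

    kind: str = "HINE"  # HINE | Helentron | canonical_Helitron | proto_Helentron
    subtir_len: int = 14
    subtir5_offset: int = 3  # the 5' terminal T run of the master copy
    subtir3_offset: int = 48  # subTIR3 end -> 3' terminus distance
    pal3_arm: int = 5
    pal3_loop: int = 0
    pal3_offset: int = 20  # stem-loop end -> 3' terminus distance
    body_len: int = 200
    microsat: Optional[tuple[str, int]] = None  # (unit, copies)
    embed_rep_orf: bool = False
    divergence: float = 0.0
    t3_run: int = 3  # 3' terminal T run of the master copy
    subtir_seq: Optional[str] = None  # share subTIRs across family members
    rep_diag2: str = "S"  # S -> Helentron-class ORF, L -> Helitron-class

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.3):
            raise ValueError("divergence must be in [0, 0.3]")
        if self.kind in ("HINE", "Helentron"):
            if not (2 <= self.subtir5_offset <= 5):
                raise ValueError("subtir5_offset outside the 2-5 window")
            if not (38 <= self.subtir3_offset <= 60):
                raise ValueError("subtir3_offset outside the 38-60 window")
            if not (8 <= self.pal3_offset <= 35):
                raise ValueError("pal3_offset outside the 8-35 window")
            if not (12 <= self.subtir_len <= 15):
                raise ValueError("subtir_len outside the 12-15 window")
            span = 2 * self.pal3_arm + self.pal3_loop
            if not (5 <= span <= 10):
                raise ValueError("3' palindrome span outside the 5-10 window")
        elif self.kind not in ("canonical_Helitron", "proto_Helentron"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind == "Helentron" and not self.embed_rep_orf:
            raise ValueError("Helentron spec requires embed_rep_orf=True")


@dataclass
class ElementTruth:
    """Exact feature coordinates of a built element (element-local)."""

    element_id: str
    kind: str
    length: int
    t5_run: int
    t3_run: int
    features: dict[str, tuple[int, int]] = field(default_factory=dict)
    subtir_seq: Optional[str] = None
    orf: Optional[tuple[int, int]] = None
    spec: Optional[ElementSpec] = None


@dataclass
class Insertion:
    interval: GenomicInterval
    element_id: str
    kind: str
    left_t_run: int
    right_t_run: int
    copy_index: int
    has_empty_site: bool


@dataclass
class EmptySiteTruth:
    insertion_index: int
    interval: GenomicInterval


@dataclass
class SyntheticTruth:
    genome_id: str
    insertions: list[Insertion] = field(default_factory=list)
    empty_sites: list[EmptySiteTruth] = field(default_factory=list)
    families: dict[str, int] = field(default_factory=dict)
    seed: Optional[int] = None

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            raise TypeError(o)

        return json.dumps(
            {
                "genome_id": self.genome_id,
                "insertions": [dataclasses.asdict(i) for i in self.insertions],
                "empty_sites": [dataclasses.asdict(e) for e in self.empty_sites],
                "families": self.families,
                "seed": self.seed,
            },
            indent=2,
            default=enc,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        truth = cls(genome_id=data["genome_id"], seed=data["seed"])
        truth.families = {k: int(v) for k, v in data["families"].items()}
        for i in data["insertions"]:
            iv = i.pop("interval")
            truth.insertions.append(
                Insertion(interval=GenomicInterval(**iv), **i)
            )
        for e in data["empty_sites"]:
            iv = e.pop("interval")
            truth.empty_sites.append(
                EmptySiteTruth(interval=GenomicInterval(**iv), **e)
            )
        return truth

    def to_bed(self) -> str:
        lines = ["# planted insertions (BED6)"]
        for i, ins in enumerate(self.insertions):
            gi = ins.interval
            lines.append(
                f"{gi.seqid}\t{gi.start}\t{gi.end}\t{ins.element_id}.{ins.copy_index}"
                f"\t0\t{gi.strand}"
            )
        for e in self.empty_sites:
            gi = e.interval
            lines.append(f"{gi.seqid}\t{gi.start}\t{gi.end}\tempty.{e.insertion_index}\t0\t+")
        return "\n".join(lines) + "\n"


def _as_rng(rng: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_background(length: int, gc: float = 0.5, seed=None) -> str:
    """I.i.d. random DNA at the requested GC content."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0, 1)")
    rng = _as_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=length, p=p))


def _random_dna(rng: np.random.Generator, n: int, bases=_BASES) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(bases, size=n))


def _random_palindromic_subtir(rng: np.random.Generator, total_len: int) -> str:
    """A self-palindromic subTIR (odd lengths carry a 1-base loop).

    The first arm base is drawn from {C, G} so the subTIR never starts or
    ends with T (keeps terminal T-run bookkeeping exact in the simulator).
    """
    arm = total_len // 2
    first = rng.choice(np.array(list("CG")))
    rest = _random_dna(rng, arm - 1)
    left = first + rest
    center = _random_dna(rng, total_len % 2)
    return left + center + reverse_complement(left)


def _rep_orf_dna(rng: np.random.Generator, length_aa: int, diag2: str) -> str:
    """An ATG-initiated stop-free ORF whose translation carries motif 2."""
    aa_pool = np.array(list("ACDEFGHIKLNQRSTVWY"))
    motif = _REP_MOTIF_AA.replace("S", diag2, 1) if diag2 != "S" else _REP_MOTIF_AA
    n_rand = length_aa - len(motif) - 1  # leading M
    mid = n_rand // 2
    aa = "M" + _random_dna(rng, mid, aa_pool) + motif + _random_dna(
        rng, n_rand - mid, aa_pool
    )
    return "".join(_CODON[ch] for ch in aa) + "TAA"


def make_element(
    spec: ElementSpec, rng: Union[int, np.random.Generator, None] = None,
    element_id: str = "elem",
) -> tuple[str, ElementTruth]:
    """Build a master element honoring every offset in ``spec``.

    Layout (HINE/Helentron):
    ``T*t5 | subTIR5 | body | subTIR3 | spacer | stem-loop | tail | T*t3``
    with the spacer/tail sized so the profile 3' windows hold, and the tail
    drawn T-free so boundary T runs stay unambiguous.
    """
    rng = _as_rng(rng)
    if spec.kind in ("canonical_Helitron", "proto_Helentron"):
        return _make_helitron_like(spec, rng, element_id)
    subtir = spec.subtir_seq or _random_palindromic_subtir(rng, spec.subtir_len)
    if len(subtir) != spec.subtir_len:
        raise ValueError("subtir_seq length disagrees with subtir_len")
    pal_arm = _random_dna(rng, spec.pal3_arm - 1)
    pal_arm = str(rng.choice(np.array(list("CG")))) + pal_arm
    pal = pal_arm + _random_dna(rng, spec.pal3_loop) + reverse_complement(pal_arm)
    pal_span = len(pal)
    tail_len = spec.pal3_offset - spec.t3_run
    spacer_len = spec.subtir3_offset - pal_span - spec.pal3_offset
    if tail_len < 0 or spacer_len < 0:
        raise ValueError("inconsistent 3' offsets (pal3_offset/t3_run/subtir3_offset)")

    body = _random_dna(rng, spec.body_len)
    orf_span = None
    if spec.embed_rep_orf:
        orf_dna = _rep_orf_dna(rng, 320, spec.rep_diag2)
        if spec.body_len < len(orf_dna) + 20:
            raise ValueError(
                f"body_len {spec.body_len} too small for an embedded Rep ORF "
                f"({len(orf_dna)} nt)"
            )
        at = int(rng.integers(10, spec.body_len - len(orf_dna) - 9))
        body = body[:at] + orf_dna + body[at + len(orf_dna):]
        orf_span = (at, at + len(orf_dna))
    if spec.microsat is not None:
        unit, copies = spec.microsat
        ms = unit * copies
        if len(ms) > spec.body_len // 2:
            raise ValueError("microsatellite longer than half the body")
        at = int(rng.integers(0, spec.body_len - len(ms)))
        if orf_span is None or at + len(ms) <= orf_span[0] or at >= orf_span[1]:
            body = body[:at] + ms + body[at + len(ms):]

    t5 = "T" * spec.subtir5_offset
    t3 = "T" * spec.t3_run
    spacer = _random_dna(rng, spacer_len)
    tail = _random_dna(rng, tail_len, _NON_T)
    seq = t5 + subtir + body + subtir + spacer + pal + tail + t3

    o = len(t5)
    features = {"subtir5": (o, o + len(subtir))}
    o += len(subtir)
    body_span = (o, o + len(body))
    o += len(body)
    features["subtir3"] = (o, o + len(subtir))
    o += len(subtir) + spacer_len
    features["palindrome3"] = (o, o + pal_span)
    features["body"] = body_span
    truth = ElementTruth(
        element_id=element_id,
        kind=spec.kind,
        length=len(seq),
        t5_run=spec.subtir5_offset,
        t3_run=spec.t3_run,
        features=features,
        subtir_seq=subtir,
        orf=(
            None
            if orf_span is None
            else (body_span[0] + orf_span[0], body_span[0] + orf_span[1])
        ),
        spec=spec,
    )
    return seq, truth


def _make_helitron_like(
    spec: ElementSpec, rng: np.random.Generator, element_id: str
) -> tuple[str, ElementTruth]:
    """Canonical-Helitron / proto-Helentron architecture: terminal motifs and
    a 16-20 nt palindrome ~11 bp from the 3' end."""
    five = "TC" if spec.kind == "canonical_Helitron" else "TT"
    three = "CT" + "".join(rng.choice(np.array(list("AG")), size=2)) \
        if spec.kind == "canonical_Helitron" else "CTAG"
    pal_arm_len = int(rng.integers(8, 11))
    loop = int(rng.integers(0, min(2, 20 - 2 * pal_arm_len) + 1))  # span 16-20
    arm = str(rng.choice(np.array(list("CG")))) + _random_dna(rng, pal_arm_len - 1)
    pal = arm + _random_dna(rng, loop) + reverse_complement(arm)
    body = _random_dna(rng, spec.body_len)
    orf_span = None
    if spec.embed_rep_orf:
        orf_dna = _rep_orf_dna(rng, 320, spec.rep_diag2)
        if spec.body_len < len(orf_dna) + 20:
            raise ValueError("body_len too small for an embedded Rep ORF")
        at = int(rng.integers(10, spec.body_len - len(orf_dna) - 9))
        body = body[:at] + orf_dna + body[at + len(orf_dna):]
        orf_span = (at, at + len(orf_dna))
    gap = _random_dna(rng, 11 - len(three))  # palindrome ends ~11 bp from 3' end
    seq = five + body + pal + gap + three
    pal_start = len(five) + len(body)
    truth = ElementTruth(
        element_id=element_id,
        kind=spec.kind,
        length=len(seq),
        t5_run=0,
        t3_run=0,
        features={"palindrome3": (pal_start, pal_start + len(pal))},
        orf=(
            None if orf_span is None else (len(five) + orf_span[0], len(five) + orf_span[1])
        ),
        spec=spec,
    )
    return seq, truth


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: Optional[set[int]] = None,
) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(seq)) < rate
    if protected:
        for i in protected:
            if 0 <= i < len(seq):
                hit[i] = False
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def _protected_positions(truth: ElementTruth, core_offset: int) -> set[int]:
    """Feature positions (core coordinates) exempt from divergence by default:
    subTIRs, the 3' stem loop, spacer/tail (boundary bookkeeping) — i.e.
    everything except the element body."""
    body = truth.features.get("body")
    core_len = truth.length - truth.t5_run - truth.t3_run
    protected = set(range(core_len))
    if body is not None:
        for i in range(body[0] - core_offset, body[1] - core_offset):
            protected.discard(i)
    return protected


def find_tt_sites(background: str, min_sep: int = 300) -> list[int]:
    """Insertion points between the Ts of isolated TT dinucleotides (VTTV)."""
    out = []
    for i in range(1, len(background) - 2):
        if (
            background[i] == "T"
            and background[i + 1] == "T"
            and background[i - 1] != "T"
            and background[i + 2] != "T"
        ):
            out.append(i + 1)
    return out


def find_at_sites(background: str) -> list[int]:
    """Insertion points between an A and a T (canonical-Helitron targets)."""
    return [
        i + 1
        for i in range(len(background) - 1)
        if background[i] == "A" and background[i + 1] == "T"
    ]


def plant_insertions(
    background: str,
    elements: Sequence[tuple[str, ElementTruth]],
    n_copies: Union[int, Sequence[int]] = 1,
    dup_fraction: float = 0.0,
    seed: Union[int, np.random.Generator, None] = None,
    minus_fraction: float = 0.0,
    min_sep: int = 300,
    dup_window: int = 150,
    genome_id: str = "synth",
    mutate_features: bool = False,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Insert element copies into a background genome, with ground truth.

    Each copy gets fresh terminal T runs (uniform 2-5 per end), per-copy
    divergence from its own child RNG stream, and — with probability
    ``dup_fraction`` — a duplicated pre-insertion window appended after the
    genome body (the paralogous empty site).  By default substitutions avoid
    structural features (subTIRs, stem loop, spacer/tail) so planted
    architecture coordinates remain exact; set ``mutate_features=True`` for
    uniform divergence.
    """
    if isinstance(n_copies, int):
        n_copies = [n_copies] * len(elements)
    if len(n_copies) != len(elements):
        raise ValueError("n_copies must match elements")
    n_total = sum(n_copies)
    if isinstance(seed, np.random.Generator):
        raise TypeError("plant_insertions needs an integer seed (spawns child streams)")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    site_stream, pad_stream, *copy_streams = [
        np.random.default_rng(s) for s in ss.spawn(n_total + 2)
    ]

    tt_sites = [p for p in find_tt_sites(background) if p >= dup_window and p <= len(background) - dup_window]
    at_sites = [p for p in find_at_sites(background) if p >= dup_window and p <= len(background) - dup_window]
    site_stream.shuffle(tt_sites)
    site_stream.shuffle(at_sites)

    chosen: list[tuple[int, int, int]] = []  # (insertion_point, element_idx, copy_idx)
    used: list[int] = []

    def take_site(pool: list[int]) -> int:
        while pool:
            p = pool.pop()
            if all(abs(p - u) >= min_sep for u in used):
                used.append(p)
                return p
        raise ValueError("not enough insertion sites in the background")

    copy_counter = 0
    plans = []
    for ei, ((eseq, etruth), n) in enumerate(zip(elements, n_copies)):
        for ci in range(n):
            rng = copy_streams[copy_counter]
            copy_counter += 1
            helitron_mode = etruth.kind in ("canonical_Helitron", "proto_Helentron")
            ip = take_site(at_sites if helitron_mode else tt_sites)
            k5 = 0 if helitron_mode else int(rng.integers(2, 6))
            k3 = 0 if helitron_mode else int(rng.integers(2, 6))
            core = eseq[etruth.t5_run : len(eseq) - etruth.t3_run] if etruth.t3_run else eseq[etruth.t5_run :]
            protected = None if mutate_features else _protected_positions(etruth, etruth.t5_run)
            div = etruth.spec.divergence if etruth.spec else 0.0
            mutated = _mutate(core, div, rng, protected)
            copy_seq = "T" * k5 + mutated + "T" * k3
            strand = "-" if rng.random() < minus_fraction else "+"
            dup = rng.random() < dup_fraction
            plans.append((ip, ei, ci, copy_seq, strand, k5, k3, dup, etruth))

    plans.sort(key=lambda t: t[0])
    pieces = []
    cursor = 0
    offset = 0
    truth = SyntheticTruth(genome_id=genome_id, seed=seed if isinstance(seed, int) else None)
    dup_requests = []  # (insertion_index, window_seq)
    for ip, ei, ci, copy_seq, strand, k5, k3, dup, etruth in plans:
        pieces.append(background[cursor:ip])
        insert = copy_seq if strand == "+" else reverse_complement(copy_seq)
        start = ip + offset
        end = start + len(insert)
        pieces.append(insert)
        offset += len(insert)
        cursor = ip
        idx = len(truth.insertions)
        truth.insertions.append(
            Insertion(
                interval=GenomicInterval(genome_id, start, end, strand),
                element_id=etruth.element_id,
                kind=etruth.kind,
                left_t_run=k5,
                right_t_run=k3,
                copy_index=ci,
                has_empty_site=dup,
            )
        )
        if dup:
            dup_requests.append((idx, background[ip - dup_window : ip + dup_window]))
    pieces.append(background[cursor:])
    genome_seq = "".join(pieces)
    for idx, window in dup_requests:
        pad = _random_dna(pad_stream, 60)
        genome_seq += pad
        start = len(genome_seq)
        genome_seq += window
        truth.empty_sites.append(
            EmptySiteTruth(
                insertion_index=idx,
                interval=GenomicInterval(genome_id, start, start + len(window)),
            )
        )

    fam_map: dict[str, int] = {}
    for (eseq, etruth) in elements:
        key = etruth.subtir_seq or etruth.element_id
        if key not in fam_map:
            fam_map[key] = len(fam_map) + 1
        truth.families[etruth.element_id] = fam_map[key]
    return SequenceRecord(genome_id, genome_seq), truth


def make_deletion_derivative(
    element_seq: str,
    truth: ElementTruth,
    keep_5p: int,
    keep_3p: int,
    element_id: Optional[str] = None,
) -> tuple[str, ElementTruth]:
    """Excise the internal segment, keeping both structured termini.

    The keep windows must cover the structural features (5' subTIR; 3'
    subTIR and stem loop); the derivative is typed as a HINE (its coding
    capacity, if any, is destroyed).
    """
    n = len(element_seq)
    if keep_5p + keep_3p >= n:
        raise ValueError("keep windows cover the whole element; nothing to delete")
    sub5 = truth.features.get("subtir5")
    sub3 = truth.features.get("subtir3")
    pal3 = truth.features.get("palindrome3")
    if sub5 is not None and sub5[1] > keep_5p:
        raise ValueError("keep_5p does not cover the 5' subTIR")
    cut3 = n - keep_3p
    for feat in (sub3, pal3):
        if feat is not None and feat[0] < cut3:
            raise ValueError("keep_3p does not cover the 3' structural features")
    derived = element_seq[:keep_5p] + element_seq[cut3:]
    shift = cut3 - keep_5p
    features = {}
    for name, (a, b) in truth.features.items():
        if name == "body":
            continue
        if b <= keep_5p:
            features[name] = (a, b)
        elif a >= cut3:
            features[name] = (a - shift, b - shift)
    new_spec = dataclasses.replace(truth.spec, kind="HINE", embed_rep_orf=False) if truth.spec else None
    return derived, ElementTruth(
        element_id=element_id or truth.element_id + ".del",
        kind="HINE",
        length=len(derived),
        t5_run=truth.t5_run,
        t3_run=truth.t3_run,
        features=features,
        subtir_seq=truth.subtir_seq,
        orf=None,
        spec=new_spec,
    )
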