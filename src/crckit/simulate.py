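"""Synthetic genomes with planted LTR retrotransposons of known truth.

The simulator emulates the data the downstream annotators assume: a
low-repeat background, autonomous elements with paired LTRs, target-site
duplications, PBS/PPT signals and an ordered coding region; non-autonomous
derivatives; age-dependent neutral decay of the two LTRs (which are
identical at insertion time); truncation and fragmentation; nesting; and
optional tandem satellite arrays.

Substitutions follow a Kimura two-parameter process: events arrive as a
Poisson process at ``rate_per_site_per_year`` per site, each event being a
transition with probability kappa/(kappa+2).  Multiple hits at one site are
allowed, so divergence saturates exactly the way the K2P distance estimator
assumes.  No indels are simulated inside LTRs; large deletions are modelled
by the truncation/fragment decay classes instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .seqs import BASES, TRANSITION

DEFAULT_RATE = 1.3e-8  # substitutions per site per year
DEFAULT_KAPPA = 2.0  # transition/transversion rate ratio
DECAY_CLASSES = ("complete", "truncated_5p", "truncated_3p", "internal_deleted", "fragment")
TARGETING_MOTIFS = ("chromodomain", "CR_motif", "none")

_TRANSVERSIONS = {b: [x for x in BASES if x != b and x != TRANSITION[b]] for b in BASES}


@dataclass(frozen=True)
class ElementTemplate:
    """Master copy of one retroelement family.

    ``ltr_seq`` is the single LTR used for both ends at age 0;
    ``domain_layout`` holds ordered, non-overlapping (label, start, end)
    intervals on ``internal_seq`` (0-based half-open).
    """

    name: str
    ltr_seq: str
    internal_seq: str
    domain_layout: tuple = ()
    targeting_motif: str = "none"
    tsd_len: int = 5

    def __post_init__(self):
        if not 100 <= len(self.ltr_seq) <= 2500:
            raise ValueError(f"{self.name}: LTR length {len(self.ltr_seq)} outside [100, 2500]")
        if self.targeting_motif not in TARGETING_MOTIFS:
            raise ValueError(f"{self.name}: unknown targeting motif {self.targeting_motif!r}")
        if not 4 <= self.tsd_len <= 6:
            raise ValueError(f"{self.name}: tsd_len must be 4-6 bp")
        prev = 0
        for label, s, e in self.domain_layout:
            if not (prev <= s < e <= len(self.internal_seq)):
                raise ValueError(f"{self.name}: domain {label} interval [{s},{e}) invalid")
            prev = e

    @property
    def total_length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    @property
    def sequence(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq


@dataclass
class InsertionEvent:
    """One planned insertion.  ``locus`` is a 0-based position in the
    background for top-level events; for nested events (``nest_into`` set)
    it is an offset within the host's realized element, strictly inside."""

    template: str
    locus: int
    age_years: float = 0.0
    decay: str = "complete"
    nest_into: str | None = None
    fragment_fraction: float = 1.0
    event_id: str = ""

    def __post_init__(self):
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.decay not in DECAY_CLASSES:
            raise ValueError(f"unknown decay class {self.decay!r}")
        if self.decay == "fragment":
            if not 0 < self.fragment_fraction <= 1:
                raise ValueError("fragment_fraction must be in (0, 1]")
        elif self.fragment_fraction != 1.0:
            raise ValueError("fragment_fraction must be 1 unless decay='fragment'")


@dataclass
class RealizedInsertion:
    """Ground truth for one planted copy after all insertions/nestings."""

    event: InsertionEvent
    interval: tuple  # realized genomic interval, 0-based half-open
    ltr5: tuple | None = None  # genomic intervals of the LTR pair (None if lost)
    ltr3: tuple | None = None
    tsd: str | None = None
    family: str = ""


@dataclass
class SyntheticTruth:
    genome_id: str
    seed: int
    events: list = field(default_factory=list)

    def by_id(self, event_id: str) -> RealizedInsertion:
        for r in self.events:
            if r.event.event_id == event_id:
                return r
        raise KeyError(event_id)


def make_background(length_bp: int, gc: float, seed: int) -> str:
    """I.i.d. random background of ``length_bp`` bases with target GC."""
    if length_bp <= 0:
        raise ValueError("background length must be positive")
    if not 0 <= gc <= 1:
        raise ValueError("gc fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length_bp, p=p)
    return arr.tobytes().decode()


def mutate(seq: str, mean_subs_per_site: float, kappa: float, rng: np.random.Generator) -> str:
    """Apply a K2P substitution process with the given expected number of
    events per site.  Multiple hits at a site are allowed; length is kept."""
    if mean_subs_per_site < 0:
        raise ValueError("expected substitutions per site must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    n = len(seq)
    if n == 0 or mean_subs_per_site == 0:
        return seq
    n_events = rng.poisson(n * mean_subs_per_site)
    if n_events == 0:
        return seq
    sites = rng.integers(0, n, size=n_events)
    is_ts = rng.random(n_events) < kappa / (kappa + 2.0)
    tv_pick = rng.integers(0, 2, size=n_events)
    out = list(seq)
    for site, ts, pick in zip(sites, is_ts, tv_pick):
        b = out[site]
        if b not in TRANSITION:  # leave ambiguity codes untouched
            continue
        out[site] = TRANSITION[b] if ts else _TRANSVERSIONS[b][pick]
    return "".join(out)


def mutate_by_age(
    seq: str,
    age_years: float,
    rate_per_site_per_year: float = DEFAULT_RATE,
    kappa: float = DEFAULT_KAPPA,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Neutral decay of ``seq`` over ``age_years`` at the given substitution
    rate (expected events per site = age x rate)."""
    if age_years < 0 or rate_per_site_per_year < 0:
        raise ValueError("age and rate must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    return mutate(seq, age_years * rate_per_site_per_year, kappa, rng)


def _realize_sequence(template: ElementTemplate, event: InsertionEvent, rate: float, kappa: float, rng):
    """Mutated element sequence for one event, with LTR sub-intervals
    (relative to the realized sequence) or None when a copy is lost.

    Both LTRs are mutated independently, so the pair diverges at 2 x age x
    rate; truncations keep the stated end, fragments keep a central slice
    with no LTR pair; internal deletions keep both LTRs around a collapsed
    interior.
    """
    age = event.age_years
    ltr5 = mutate_by_age(template.ltr_seq, age, rate, kappa, rng=rng)
    ltr3 = mutate_by_age(template.ltr_seq, age, rate, kappa, rng=rng)
    internal = mutate_by_age(template.internal_seq, age, rate, kappa, rng=rng)
    L = len(template.ltr_seq)
    full = ltr5 + internal + ltr3
    total = len(full)
    if event.decay == "complete":
        return full, (0, L), (total - L, total)
    if event.decay == "truncated_5p":
        # 5' half lost: no 5' LTR, internal tail + 3' LTR survive
        cut = L + len(internal) // 2
        kept = full[cut:]
        return kept, None, (len(kept) - L, len(kept))
    if event.decay == "truncated_3p":
        cut = L + len(internal) // 2
        return full[:cut], (0, L), None
    if event.decay == "internal_deleted":
        keep = max(1, len(internal) // 5)
        seq = ltr5 + internal[:keep] + internal[-keep:] + ltr3
        return seq, (0, L), (len(seq) - L, len(seq))
    # fragment: central slice of the stated fraction, LTR pair lost
    flen = max(1, int(round(event.fragment_fraction * total)))
    start = (total - flen) // 2
    return full[start : start + flen], None, None


def plant_elements(
    background: str,
    templates: list,
    events: list,
    rate: float = DEFAULT_RATE,
    kappa: float = DEFAULT_KAPPA,
    seed: int = 0,
    genome_id: str = "synthetic",
):
    """Insert ``events`` into ``background`` and return (genome, truth).

    Complete (and internal-deleted) insertions are flanked by an exact
    target-site duplication at age 0 (the duplicated copy decays with age).
    Nested events are inserted inside their host's realized element.
    """
    by_name = {t.name: t for t in templates}
    rng = np.random.default_rng(seed)

    top: list[InsertionEvent] = []
    children: dict[str, list[InsertionEvent]] = {}
    ids = set()
    for i, ev in enumerate(events):
        if ev.template not in by_name:
            raise ValueError(f"unknown template {ev.template!r}")
        if not ev.event_id:
            ev = replace(ev, event_id=f"ins{i:04d}")
        if ev.event_id in ids:
            raise ValueError(f"duplicate event id {ev.event_id}")
        ids.add(ev.event_id)
        if ev.nest_into is None:
            if not 0 <= ev.locus <= len(background):
                raise ValueError(f"{ev.event_id}: locus outside background")
            top.append(ev)
        else:
            if ev.nest_into not in ids:
                raise ValueError(f"{ev.event_id}: nest target {ev.nest_into!r} not planted yet")
            children.setdefault(ev.nest_into, []).append(ev)

    seen_loci = {}
    for ev in top:
        if ev.locus in seen_loci:
            raise ValueError(
                f"events {seen_loci[ev.locus]} and {ev.event_id} overlap at locus {ev.locus}"
            )
        seen_loci[ev.locus] = ev.event_id

    realized: dict[str, RealizedInsertion] = {}

    def build(ev: InsertionEvent) -> str:
        """Element sequence for ev with all nested children inserted;
        records child intervals relative to ev's sequence."""
        tmpl = by_name[ev.template]
        seq, ltr5, ltr3 = _realize_sequence(tmpl, ev, rate, kappa, rng)
        rec = RealizedInsertion(
            event=ev, interval=(0, len(seq)), ltr5=ltr5, ltr3=ltr3, family=tmpl.name
        )
        realized[ev.event_id] = rec
        kids = sorted(children.get(ev.event_id, []), key=lambda e: e.locus)
        shift = 0
        for kid in kids:
            off = kid.locus + shift
            if not 0 < off < len(seq):
                raise ValueError(f"{kid.event_id}: nest offset not strictly inside host")
            kid_tmpl = by_name[kid.template]
            kid_seq = build(kid)
            tsd = None
            ins = kid_seq
            if kid.decay in ("complete", "internal_deleted") and off >= kid_tmpl.tsd_len:
                tsd = seq[off - kid_tmpl.tsd_len : off]
                ins = kid_seq + mutate_by_age(tsd, kid.age_years, rate, kappa, rng=rng)
            seq = seq[:off] + ins + seq[off:]
            krec = realized[kid.event_id]
            _offset_record(krec, off, recurse=children, realized=realized)
            krec.tsd = tsd
            shift += len(ins)
            # grow host bookkeeping
            rec.interval = (0, len(seq))
            rec.ltr5, rec.ltr3 = _shift_ltrs(rec.ltr5, rec.ltr3, off, len(ins))
        return seq

    pieces = []
    cursor = 0
    offset = 0  # accumulated growth
    for ev in sorted(top, key=lambda e: e.locus):
        tmpl = by_name[ev.template]
        seq = build(ev)
        pieces.append(background[cursor : ev.locus])
        tsd = None
        ins = seq
        if ev.decay in ("complete", "internal_deleted") and ev.locus >= tmpl.tsd_len:
            tsd = background[ev.locus - tmpl.tsd_len : ev.locus]
            ins = seq + mutate_by_age(tsd, ev.age_years, rate, kappa, rng=rng)
        abs_start = ev.locus + offset
        _offset_record(realized[ev.event_id], abs_start, recurse=children, realized=realized)
        realized[ev.event_id].tsd = tsd
        pieces.append(ins)
        offset += len(ins)
        cursor = ev.locus
    pieces.append(background[cursor:])
    genome = "".join(pieces)

    truth = SyntheticTruth(genome_id=genome_id, seed=seed)
    truth.events = sorted(realized.values(), key=lambda r: r.interval[0])
    return genome, truth


def _shift_ltrs(ltr5, ltr3, at, by):
    def sh(iv):
        if iv is None:
            return None
        s, e = iv
        return (s + by if s >= at else s, e + by if e > at else e)

    return sh(ltr5), sh(ltr3)


def _offset_record(rec: RealizedInsertion, delta: int, recurse=None, realized=None):
    rec.interval = (rec.interval[0] + delta, rec.interval[1] + delta)
    if rec.ltr5 is not None:
        rec.ltr5 = (rec.ltr5[0] + delta, rec.ltr5[1] + delta)
    if rec.ltr3 is not None:
        rec.ltr3 = (rec.ltr3[0] + delta, rec.ltr3[1] + delta)
    if recurse is not None:
        for kid in recurse.get(rec.event.event_id, []):
            _offset_record(realized[kid.event_id], delta, recurse, realized)


def plant_tandem_array(
    background: str,
    monomer: str,
    n_copies: int,
    locus: int,
    monomer_divergence: float = 0.0,
    seed: int = 0,
):
    """Insert ``n_copies`` head-to-tail copies of ``monomer`` at ``locus``;
    each copy is independently mutated to the stated expected divergence."""
    if n_copies < 2:
        raise ValueError("a tandem array needs at least 2 copies")
    if not 0 <= locus <= len(background):
        raise ValueError("locus outside background")
    rng = np.random.default_rng(seed)
    copies = [mutate(monomer, monomer_divergence, DEFAULT_KAPPA, rng) for _ in range(n_copies)]
    array = "".join(copies)
    genome = background[:locus] + array + background[locus:]
    truth = {
        "interval": (locus, locus + len(array)),
        "period": len(monomer),
        "n_copies": n_copies,
    }
    return genome, truth
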