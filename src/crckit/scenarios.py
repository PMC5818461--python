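"""Canonical synthetic-genome scenarios.

These fix the study conditions the package is validated under: element
structure mirrors the ten described families (6-8 kb elements, 661-781 bp
LTRs, 5-bp TSDs), the neutral substitution rate is 1.3e-8 per site per
year, and plantings are spaced so that a 2-Mb chromosome carries a
realistic few dozen insertions.  Backgrounds use GC 0.38, typical of plant
euchromatin.
"""

from __future__ import annotations

import numpy as np

from .simulate import (
    DEFAULT_RATE,
    InsertionEvent,
    make_background,
    plant_elements,
    plant_tandem_array,
)
from .templates import default_family_templates, nonautonomous_templates

BACKGROUND_GC = 0.38


def _spaced_loci(n: int, length: int, rng: np.random.Generator, margin: int = 10_000):
    """n jittered loci, one per equal slot, so inserts never collide."""
    usable = length - 2 * margin
    slot = usable // n
    return [margin + i * slot + int(rng.integers(0, max(1, slot // 3))) for i in range(n)]


def scenario_detection(seed: int, genome_len: int = 2_000_000, n_complete: int = 40, n_decoys: int = 20):
    """A 2-Mb chromosome with complete elements at ages 0-2 Mya plus
    LTR-less decoys (truncations and fragments).  Returns
    (genome, truth, templates)."""
    rng = np.random.default_rng(seed)
    fams = default_family_templates()
    bg = make_background(genome_len, BACKGROUND_GC, seed)
    loci = _spaced_loci(n_complete + n_decoys, genome_len, rng)
    rng.shuffle(loci)
    events = []
    for i in range(n_complete):
        events.append(
            InsertionEvent(
                template=fams[i % len(fams)].name,
                locus=loci[i],
                age_years=float(rng.uniform(0, 2e6)),
                event_id=f"complete{i:03d}",
            )
        )
    decay_cycle = ("fragment", "truncated_5p", "truncated_3p")
    for i in range(n_decoys):
        decay = decay_cycle[i % 3]
        events.append(
            InsertionEvent(
                template=fams[(i + 3) % len(fams)].name,
                locus=loci[n_complete + i],
                age_years=float(rng.uniform(0, 2e6)),
                decay=decay,
                fragment_fraction=0.3 if decay == "fragment" else 1.0,
                event_id=f"decoy{i:03d}",
            )
        )
    genome, truth = plant_elements(bg, fams, events, rate=DEFAULT_RATE, seed=seed, genome_id="chr_sim")
    return genome, truth, fams


def scenario_dating(seed: int, ages=(0.5e6, 1e6, 2e6, 3e6), n_per_age: int = 50):
    """One genome per age point, each with n_per_age complete elements of
    that age.  Yields (age, genome, truth)."""
    fams = default_family_templates()
    for ai, age in enumerate(ages):
        gseed = seed + 101 * (ai + 1)
        rng = np.random.default_rng(gseed)
        glen = 900_000
        bg = make_background(glen, BACKGROUND_GC, gseed)
        loci = _spaced_loci(n_per_age, glen, rng)
        events = [
            InsertionEvent(template=fams[i % len(fams)].name, locus=loci[i], age_years=age, event_id=f"age{ai}_{i:03d}")
            for i in range(n_per_age)
        ]
        genome, truth = plant_elements(bg, fams, events, rate=DEFAULT_RATE, seed=gseed, genome_id=f"chr_age{ai}")
        yield age, genome, truth


def scenario_families(seed: int, n_genomes: int = 3, copies_per_family: int = 3, max_age: float = 6e6):
    """The family-recovery design: several genomes sharing the ten
    families, a few copies each, ages up to ``max_age`` so within-family
    RT identity sits near 90% while between-family identity stays near
    55%.  Yields (genome_id, genome, truth)."""
    fams = default_family_templates()
    for g in range(n_genomes):
        gseed = seed + 977 * (g + 1)
        rng = np.random.default_rng(gseed)
        n = len(fams) * copies_per_family
        glen = 320_000 + n * 8000
        bg = make_background(320_000, BACKGROUND_GC, gseed)
        loci = _spaced_loci(n, 320_000, rng, margin=5_000)
        events = []
        for i in range(n):
            events.append(
                InsertionEvent(
                    template=fams[i % len(fams)].name,
                    locus=loci[i],
                    age_years=float(rng.uniform(0, max_age)),
                    event_id=f"g{g}e{i:03d}",
                )
            )
        genome, truth = plant_elements(bg, fams, events, rate=DEFAULT_RATE, seed=gseed, genome_id=f"genome{g}")
        yield f"genome{g}", genome, truth


def scenario_centromere(seed: int, with_satellite: bool = False):
    """A CRC-rich centromere-like region: ~90% of the region is
    transposable-element sequence and ~35% is CRC, the dominant family
    contributing the most, with no tandem arrays unless requested.

    Built by explicit block concatenation so the composition is known by
    construction.  Returns (sequence, block_records, region_interval).
    block_records are (category_path, interval) tuples.
    """
    rng = np.random.default_rng(seed)
    fams = default_family_templates()
    nonauto = nonautonomous_templates()
    target_len = 800_000
    blocks = []  # (category path, sequence)

    def te_block(seq, path):
        blocks.append((path, seq))

    # CRC complete elements, family H dominant (mirrors one family
    # dominating the centromere), plus other families
    crc_target = int(0.35 * target_len)
    crc_len = 0
    i = 0
    while crc_len < crc_target:
        fam = fams[7] if i % 2 == 0 else fams[(i // 2) % len(fams)]
        seq = fam.sequence
        te_block(seq, ("TE", "LTR_RT", "CRC", fam.name))
        crc_len += len(seq)
        i += 1
    # non-autonomous derivatives and other Gypsy-like elements up to ~90% TE
    other_target = int(0.90 * target_len) - crc_len
    other_len = 0
    j = 0
    while other_len < other_target:
        if j % 3 == 0:
            t = nonauto[j // 3 % len(nonauto)]
            seq = t.sequence
            te_block(seq, ("TE", "LTR_RT", "nonautonomous", t.name))
        else:
            L = int(rng.integers(4000, 9000))
            seq = make_background(L, 0.42, int(rng.integers(2**31)))
            te_block(seq, ("TE", "LTR_RT", "other_lineage"))
        other_len += len(seq)
        j += 1
    filler_total = max(0, target_len - crc_len - other_len)
    n_gaps = len(blocks) + 1
    gap = filler_total // n_gaps

    pieces, records = [], []
    pos = 0

    def emit_bg(n):
        nonlocal pos
        if n > 0:
            pieces.append(make_background(n, BACKGROUND_GC, int(rng.integers(2**31))))
            pos += n

    emit_bg(gap)
    order = rng.permutation(len(blocks))
    for bi in order:
        path, seq = blocks[bi]
        records.append((path, (pos, pos + len(seq))))
        pieces.append(seq)
        pos += len(seq)
        emit_bg(gap)
    if with_satellite:
        monomer = make_background(170, 0.45, seed + 5)
        sat, _ = plant_tandem_array("", monomer, 60, 0, 0.02, seed=seed + 6)
        records.append((("satellite",), (pos, pos + len(sat))))
        pieces.append(sat)
        pos += len(sat)
        emit_bg(gap)
    seqs_all = "".join(pieces)
    return seqs_all, records, (0, len(seqs_all))
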