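"""End-to-end validation experiments on the canonical scenarios.

Each experiment runs the real pipeline code on freshly simulated data and
returns the summary statistics a benchmark reader cares about (recall,
precision, dating error, family-recovery accuracy, ...).  Both the test
suite and the acceptance script call these.
"""

from __future__ import annotations

import numpy as np

from . import census as census_mod
from . import classify as classify_mod
from . import domains as domains_mod
from .detect import DetectionConfig, detect_elements
from .njtree import bootstrap_groups
from .scenarios import scenario_centromere, scenario_dating, scenario_detection, scenario_families
from .simulate import DEFAULT_RATE, make_background, plant_tandem_array


def detection_experiment(seed: int, boundary_tol: int = 5, **scenario_kw):
    """Recall/precision of structural detection for planted complete
    elements, with per-boundary error accounting."""
    genome, truth, _ = scenario_detection(seed, **scenario_kw)
    detected = detect_elements(genome, DetectionConfig(), genome_id=truth.genome_id)
    complete = [r for r in truth.events if r.event.decay in ("complete", "internal_deleted")]
    matched_truth = set()
    matched_det = set()
    errors = []
    for di, el in enumerate(detected):
        for ti, r in enumerate(complete):
            if ti in matched_truth:
                continue
            e_start = abs(el.interval[0] - r.interval[0])
            e_end = abs(el.interval[1] - r.interval[1])
            if e_start <= boundary_tol and e_end <= boundary_tol:
                matched_truth.add(ti)
                matched_det.add(di)
                errors.append((e_start, e_end))
                break
    recall = len(matched_truth) / len(complete) if complete else 1.0
    precision = len(matched_det) / len(detected) if detected else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_planted_complete": len(complete),
        "n_detected": len(detected),
        "max_boundary_error": max((max(e) for e in errors), default=0),
    }


def dating_experiment(seed: int, ages=(0.5e6, 1e6, 2e6, 3e6), n_per_age: int = 50):
    """Insertion-age recovery, simulate -> detect -> date.

    Per age point: the per-element K2P age estimates of every detected
    element, the relative error of their median (parameter recovery), and
    the median per-element relative error (Poisson-floor-limited at young
    ages; reported for completeness)."""
    out = {}
    for age, genome, truth in scenario_dating(seed, ages=ages, n_per_age=n_per_age):
        detected = detect_elements(genome, DetectionConfig(), genome_id=truth.genome_id)
        ests = []
        for el in detected:
            a = census_mod.date_element(genome, el, r=DEFAULT_RATE)
            if not a.saturated:
                ests.append(a.T)
        ests = np.array(ests)
        rel_err = np.abs(ests - age) / age
        out[age] = {
            "n": int(ests.size),
            "median_estimate": float(np.median(ests)) if ests.size else float("nan"),
            "median_recovery_error": float(abs(np.median(ests) - age) / age) if ests.size else float("nan"),
            "median_element_error": float(np.median(rel_err)) if ests.size else float("nan"),
        }
    return out


def family_experiment(seed: int, n_bootstrap: int = 1000, **scenario_kw):
    """Family recovery on the multi-genome design: detect, annotate,
    extract RTs, define groups from the bootstrapped NJ tree, and score
    group memberships against the planted family labels."""
    rts: dict = {}
    truth_family: dict = {}
    motifs: dict = {}
    dcfg = domains_mod.DomainConfig()
    for gid, genome, truth in scenario_families(seed, **scenario_kw):
        detected = detect_elements(genome, DetectionConfig(), genome_id=gid)
        for el in detected:
            eseq = genome[el.interval[0] : el.interval[1]]
            hits = domains_mod.scan_domains(eseq, dcfg)
            rt = domains_mod.extract_rt(eseq, hits, dcfg)
            if rt is None:
                continue
            eid = f"{gid}:{el.interval[0]}"
            rts[eid] = rt.nt_seq
            motifs[eid] = domains_mod.detect_targeting_motif(eseq, hits, el.ltr3[0] - el.interval[0], dcfg)
            # planted label: the truth event containing this element
            for r in truth.events:
                if r.interval[0] - 30 <= el.interval[0] and el.interval[1] <= r.interval[1] + 30:
                    truth_family[eid] = r.family
                    break
    ident = classify_mod.identity_matrix(rts)
    aln = classify_mod.align_sequences(rts)
    tree, supports = bootstrap_groups(aln, n_reps=n_bootstrap, seed=seed)
    groups = classify_mod.define_groups(tree, supports, ident, motifs=motifs)
    # membership accuracy: best 1:1 mapping of recovered groups to planted families
    correct = 0
    used = set()
    for g in sorted(groups, key=lambda g: -len(g.members)):
        fams = [truth_family.get(m) for m in g.members]
        best_fam, best_n = None, 0
        for f in set(fams) - {None} - used:
            n = fams.count(f)
            if n > best_n:
                best_fam, best_n = f, n
        if best_fam is not None:
            used.add(best_fam)
            correct += best_n
    n_multi = sum(1 for g in groups if len(g.members) >= 2)
    return {
        "n_rts": len(rts),
        "n_groups": len(groups),
        "n_multimember_groups": n_multi,
        "membership_accuracy": correct / len(rts) if rts else 0.0,
        "groups": groups,
        "identity": ident,
        "rts": rts,
        "truth_family": truth_family,
    }


def satellite_experiment(seed: int):
    """The tandem-array negative control and its positive counterpart."""
    centro, _, _ = scenario_centromere(seed, with_satellite=False)
    neg = census_mod.detect_tandem_arrays(centro, min_period=50, max_period=500, min_copies=5)
    bg = make_background(200_000, 0.38, seed + 1)
    monomer = make_background(170, 0.45, seed + 2)
    planted, truth = plant_tandem_array(bg, monomer, 50, 100_000, 0.02, seed=seed + 3)
    pos = census_mod.detect_tandem_arrays(planted, min_period=50, max_period=500, min_copies=5)
    period_err = min((abs(a["period"] - truth["period"]) for a in pos), default=None)
    return {
        "n_arrays_negative_control": len(neg),
        "n_arrays_positive_control": len(pos),
        "period_error": period_err,
        "true_period": truth["period"],
    }


def composition_experiment(seed: int):
    """Region-composition report on the constructed centromere."""
    seq, blocks, region = scenario_centromere(seed)

    class _Rec:
        def __init__(self, path, iv):
            self.category = path
            self.interval = iv

    recs = [_Rec(p, iv) for p, iv in blocks]
    table = census_mod.region_composition(recs, region)
    lookup = dict(zip(table["category"], table["percent"]))
    return {
        "te_percent": lookup.get("TE", 0.0),
        "crc_percent": lookup.get("TE/LTR_RT/CRC", 0.0),
        "dominant_family_percent": max(
            (v for k, v in lookup.items() if k.startswith("TE/LTR_RT/CRC/")), default=0.0
        ),
        "table": table,
    }
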