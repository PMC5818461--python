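"""Pipeline orchestration: simulate -> detect -> annotate -> classify ->
census -> date -> density -> report.

Each stage reads only files written by earlier stages (so any stage can be
re-run standalone from an existing run directory), logs its wall time and
input/output hashes, and writes deterministic output for a fixed config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import census as census_mod
from . import classify as classify_mod
from . import domains as domains_mod
from . import io as cio
from .config import RunConfig
from .detect import detect_elements
from .njtree import bootstrap_groups
from .simulate import InsertionEvent, make_background, plant_elements, plant_tandem_array
from .templates import default_family_templates, nonautonomous_templates

STAGES = ("simulate", "detect", "annotate", "classify", "census", "date", "density", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"stage '{stage}' failed: {msg}")
        self.stage = stage


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.outdir = Path(cfg.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.log_path = self.outdir / "run.log"

    def log(self, msg: str):
        with open(self.log_path, "a") as fh:
            fh.write(msg + "\n")

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _stage(self, name, fn, inputs=(), outputs=()):
        t0 = time.time()
        for f in inputs:
            p = self.path(f)
            if not p.exists():
                raise StageError(name, f"missing input {f}")
            self.log(f"{name}\tinput\t{f}\t{_sha(p)}")
        try:
            fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, str(exc)) from exc
        for f in outputs:
            p = self.path(f)
            if not p.exists():
                raise StageError(name, f"did not produce {f}")
            self.log(f"{name}\toutput\t{f}\t{_sha(p)}")
        self.log(f"{name}\tdone\t{time.time() - t0:.2f}s\tseed={self.cfg.derived_seed(name)}")


def stage_simulate(run: Run):
    cfg = run.cfg
    sc = cfg.scenario
    seed = cfg.derived_seed("simulate")
    rng = np.random.default_rng(seed)
    fams = default_family_templates()
    nonauto = nonautonomous_templates()
    templates = fams + nonauto
    bg = make_background(sc.genome_len, sc.gc, seed)
    n_total = sc.n_complete + sc.n_decoys + sc.n_nonautonomous
    margin = 10_000
    slot = (sc.genome_len - 2 * margin) // max(1, n_total)
    loci = [margin + i * slot + int(rng.integers(0, max(1, slot // 3))) for i in range(n_total)]
    rng.shuffle(loci)
    events = []
    decay_cycle = ("fragment", "truncated_5p", "truncated_3p")
    for i in range(n_total):
        if i < sc.n_complete:
            tmpl, decay, frac = fams[i % len(fams)].name, "complete", 1.0
        elif i < sc.n_complete + sc.n_decoys:
            decay = decay_cycle[i % 3]
            tmpl, frac = fams[i % len(fams)].name, 0.3 if decay == "fragment" else 1.0
        else:
            tmpl, decay, frac = nonauto[i % len(nonauto)].name, "complete", 1.0
        events.append(
            InsertionEvent(
                template=tmpl, locus=loci[i], age_years=float(rng.uniform(0, sc.max_age_years)),
                decay=decay, fragment_fraction=frac, event_id=f"ins{i:04d}",
            )
        )
    genome, truth = plant_elements(bg, templates, events, rate=sc.rate, kappa=sc.kappa, seed=seed, genome_id="chr_sim")
    if sc.tandem_array:
        monomer = make_background(170, 0.45, seed + 1)
        genome, _ = plant_tandem_array(genome, monomer, 50, len(genome) // 2, 0.02, seed=seed + 2)

    cio.write_fasta(run.path("genome.fa"), {truth.genome_id: genome})
    recs = []
    for r in truth.events:
        recs.append(
            cio.AnnotationRecord(
                record_id=r.event.event_id, genome_id=truth.genome_id, interval=r.interval, strand="+",
                feature_type="LTR_retrotransposon",
                attributes={
                    "family": r.family, "age_years": f"{r.event.age_years:.0f}",
                    "decay": r.event.decay, "nest_parent": r.event.nest_into or ".",
                },
            )
        )
    cio.write_gff3(run.path("truth.gff3"), recs)
    pd.DataFrame(
        [
            {
                "event_id": r.event.event_id, "family": r.family, "start": r.interval[0], "end": r.interval[1],
                "age_years": r.event.age_years, "decay": r.event.decay, "tsd": r.tsd or ".",
            }
            for r in truth.events
        ]
    ).to_csv(run.path("truth.tsv"), sep="\t", index=False)


def stage_detect(run: Run):
    cfg = run.cfg
    src = cfg.genome_fasta or run.path("genome.fa")
    seqs_by_id, _ = cio.read_fasta(src)
    recs = []
    rows = []
    for gid, seq in seqs_by_id.items():
        for i, el in enumerate(detect_elements(seq, cfg.detection, genome_id=gid)):
            eid = f"{gid}_el{i:04d}"
            recs.append(
                cio.AnnotationRecord(
                    record_id=eid, genome_id=gid, interval=el.interval, strand=el.strand,
                    feature_type="LTR_retrotransposon",
                    attributes={"ltr_pair_identity": f"{el.ltr_pair_identity:.2f}", "tsd": el.tsd or "."},
                )
            )
            for part, iv in (("long_terminal_repeat", el.ltr5), ("long_terminal_repeat", el.ltr3),
                             ("primer_binding_site", el.pbs), ("RR_tract", el.ppt)):
                if iv is not None:
                    recs.append(
                        cio.AnnotationRecord(
                            record_id=f"{eid}_{part}_{iv[0]}", genome_id=gid, interval=iv,
                            strand=el.strand, feature_type=part, parent=eid,
                        )
                    )
            rows.append(
                {
                    "element_id": eid, "genome": gid, "start": el.interval[0], "end": el.interval[1],
                    "strand": el.strand, "ltr5_start": el.ltr5[0], "ltr5_end": el.ltr5[1],
                    "ltr3_start": el.ltr3[0], "ltr3_end": el.ltr3[1],
                    "ltr_pair_identity": el.ltr_pair_identity, "tsd": el.tsd or ".",
                    "pbs": "." if el.pbs is None else f"{el.pbs[0]}-{el.pbs[1]}",
                    "ppt": "." if el.ppt is None else f"{el.ppt[0]}-{el.ppt[1]}",
                }
            )
    cio.write_gff3(run.path("elements.gff3"), recs)
    pd.DataFrame(rows).to_csv(run.path("elements.tsv"), sep="\t", index=False)


def stage_annotate(run: Run):
    cfg = run.cfg
    src = cfg.genome_fasta or run.path("genome.fa")
    seqs_by_id, _ = cio.read_fasta(src)
    elements = pd.read_csv(run.path("elements.tsv"), sep="\t")
    dom_rows = []
    rt_fa = {}
    for _, row in elements.iterrows():
        seq = seqs_by_id[row["genome"]][row["start"] : row["end"]]
        hits = domains_mod.scan_domains(seq, cfg.domains)
        ltr3_start_rel = row["ltr3_start"] - row["start"]
        motif = domains_mod.detect_targeting_motif(seq, hits, ltr3_start_rel, cfg.domains)
        superfam = classify_mod.assign_superfamily(hits)
        for h in hits:
            dom_rows.append(
                {
                    "element_id": row["element_id"], "domain": h.domain,
                    "start": row["start"] + h.genomic_interval[0], "end": row["start"] + h.genomic_interval[1],
                    "frame": h.frame, "aa_identity": h.aa_identity, "aa_length": h.aa_length,
                    "reference_id": h.reference_id,
                }
            )
        rt = domains_mod.extract_rt(seq, hits, cfg.domains)
        if rt is not None:
            rt_fa[row["element_id"]] = rt.nt_seq
        dom_rows.append(
            {
                "element_id": row["element_id"], "domain": f"__summary:{superfam}:{motif}",
                "start": row["start"], "end": row["end"], "frame": 0, "aa_identity": 0.0,
                "aa_length": 0, "reference_id": ".",
            }
        )
    pd.DataFrame(dom_rows).to_csv(run.path("domains.tsv"), sep="\t", index=False)
    cio.write_fasta(run.path("rt_domains.fa"), rt_fa)


def stage_classify(run: Run):
    cfg = run.cfg
    doms = pd.read_csv(run.path("domains.tsv"), sep="\t")
    summaries = doms[doms["domain"].str.startswith("__summary")]
    meta = {
        r["element_id"]: r["domain"].split(":")[1:] for _, r in summaries.iterrows()
    }
    pd.DataFrame(
        [{"element_id": k, "superfamily": v[0], "targeting_motif": v[1]} for k, v in meta.items()]
    ).to_csv(run.path("superfamilies.tsv"), sep="\t", index=False)

    rt_path = run.path("rt_domains.fa")
    rts, _ = cio.read_fasta(rt_path)
    if len(rts) >= 4:
        ident = classify_mod.identity_matrix(rts)
        aln = classify_mod.align_sequences(rts)
        tree, supports = bootstrap_groups(aln, n_reps=cfg.groups.n_bootstrap, seed=cfg.derived_seed("classify"))
        motifs = {k: v[1] for k, v in meta.items()}
        groups = classify_mod.define_groups(tree, supports, ident, cfg.groups, motifs=motifs)
        run.path("rt_tree.nwk").write_text(tree.newick(supports) + "\n")
        cio.write_tsv(run.path("rt_identity.tsv"), ident)
        gmat = classify_mod.group_identity_matrix(groups, rts)
        cio.write_tsv(run.path("group_identity.tsv"), gmat)
        pd.DataFrame(
            [
                {
                    "group": g.name, "n_members": len(g.members), "representative": g.representative,
                    "within_identity": g.within_identity, "targeting_motif": g.targeting_motif,
                    "members": ",".join(g.members),
                }
                for g in groups
            ]
        ).to_csv(run.path("groups.tsv"), sep="\t", index=False)
    else:
        pd.DataFrame(columns=["group", "n_members", "representative", "within_identity", "targeting_motif", "members"]).to_csv(
            run.path("groups.tsv"), sep="\t", index=False
        )


def stage_census(run: Run):
    cfg = run.cfg
    src = cfg.genome_fasta or run.path("genome.fa")
    seqs_by_id, _ = cio.read_fasta(src)
    groups = pd.read_csv(run.path("groups.tsv"), sep="\t")
    elements = pd.read_csv(run.path("elements.tsv"), sep="\t").set_index("element_id")
    copies = []
    for _, g in groups.iterrows():
        rep_row = elements.loc[g["representative"]]
        rep_seq = seqs_by_id[rep_row["genome"]][rep_row["start"] : rep_row["end"]]
        for gid, seq in seqs_by_id.items():
            hits = census_mod.census_scan(rep_seq, seq, cfg.census, family=g["group"], genome_id=gid)
            copies.extend(census_mod.call_copies(hits, cfg.census))
    df = pd.DataFrame(
        [
            {
                "family": c.family, "genome": c.genome_id, "start": c.interval[0], "end": c.interval[1],
                "strand": c.strand, "identity": c.identity, "coverage": c.coverage, "completeness": c.completeness,
            }
            for c in copies
        ]
    )
    df.to_csv(run.path("copies.tsv"), sep="\t", index=False)
    recs = [
        cio.AnnotationRecord(
            record_id=f"copy{i:05d}", genome_id=c.genome_id, interval=c.interval, strand=c.strand,
            score=round(100 * c.identity, 1), feature_type="match",
        )
        for i, c in enumerate(copies)
    ]
    cio.write_bed(run.path("copies.bed"), recs)
    if len(df):
        table = df.pivot_table(index="family", columns="completeness", aggfunc="size", fill_value=0)
        table.to_csv(run.path("copy_table.tsv"), sep="\t")


def stage_date(run: Run):
    cfg = run.cfg
    src = cfg.genome_fasta or run.path("genome.fa")
    seqs_by_id, _ = cio.read_fasta(src)
    elements = pd.read_csv(run.path("elements.tsv"), sep="\t")
    rows = []
    for _, row in elements.iterrows():
        seq = seqs_by_id[row["genome"]]

        class _E:
            ltr5 = (row["ltr5_start"], row["ltr5_end"])
            ltr3 = (row["ltr3_start"], row["ltr3_end"])

        age = census_mod.date_element(seq, _E, r=cfg.scenario.rate, element_id=row["element_id"])
        rows.append(
            {
                "element_id": row["element_id"], "P": age.P, "Q": age.Q, "K": age.K,
                "T_years": age.T, "rate": age.r, "saturated": age.saturated,
            }
        )
    pd.DataFrame(rows).to_csv(run.path("ages.tsv"), sep="\t", index=False)


def stage_density(run: Run):
    cfg = run.cfg
    src = cfg.genome_fasta or run.path("genome.fa")
    seqs_by_id, _ = cio.read_fasta(src)
    copies = pd.read_csv(run.path("copies.tsv"), sep="\t")
    for gid, seq in seqs_by_id.items():
        sub = copies[copies["genome"] == gid]
        ivs = list(zip(sub["start"], sub["end"]))
        track = census_mod.density_profile(
            ivs, len(seq), min(cfg.density_window_bp, len(seq)), min(cfg.density_step_bp, len(seq)),
            mode="coverage", genome_id=gid,
        )
        cio.write_bedgraph(run.path(f"density_{gid}.bedgraph"), track)


def stage_report(run: Run):
    cfg = run.cfg
    src = cfg.genome_fasta or run.path("genome.fa")
    seqs_by_id, _ = cio.read_fasta(src)
    copies = pd.read_csv(run.path("copies.tsv"), sep="\t")
    sup = pd.read_csv(run.path("superfamilies.tsv"), sep="\t")
    elements = pd.read_csv(run.path("elements.tsv"), sep="\t")
    arrays = []
    reports = {}
    for gid, seq in seqs_by_id.items():
        recs = []

        class _R:
            def __init__(self, cat, iv):
                self.category = cat
                self.interval = iv

        for _, c in copies[copies["genome"] == gid].iterrows():
            recs.append(_R(("TE", "LTR_RT", "CRC", c["family"]), (c["start"], c["end"])))
        table = census_mod.region_composition(recs, (0, len(seq))) if recs else pd.DataFrame()
        reports[gid] = table
        if len(table):
            table.to_csv(run.path(f"composition_{gid}.tsv"), sep="\t", index=False)
        arrays.extend(
            dict(a, genome=gid) for a in census_mod.detect_tandem_arrays(seq, min_period=50, max_period=500, min_copies=5)
        )
    summary = {
        "n_elements": int(len(elements)),
        "n_copies": int(len(copies)),
        "superfamilies": sup["superfamily"].value_counts().to_dict(),
        "tandem_arrays": [
            {"genome": a["genome"], "start": a["interval"][0], "end": a["interval"][1],
             "period": a["period"], "copies": a["copies"]}
            for a in arrays
        ],
    }
    run.path("summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


_STAGE_FN = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "annotate": stage_annotate,
    "classify": stage_classify,
    "census": stage_census,
    "date": stage_date,
    "density": stage_density,
    "report": stage_report,
}

_STAGE_IO = {
    "simulate": ((), ("genome.fa", "truth.gff3", "truth.tsv")),
    "detect": (("genome.fa",), ("elements.gff3", "elements.tsv")),
    "annotate": (("genome.fa", "elements.tsv"), ("domains.tsv", "rt_domains.fa")),
    "classify": (("domains.tsv",), ("groups.tsv",)),
    "census": (("genome.fa", "groups.tsv", "elements.tsv"), ("copies.tsv",)),
    "date": (("genome.fa", "elements.tsv"), ("ages.tsv",)),
    "density": (("genome.fa", "copies.tsv"), ()),
    "report": (("genome.fa", "copies.tsv"), ("summary.json",)),
}


def run_stage(cfg: RunConfig, stage: str) -> Path:
    run = Run(cfg)
    if stage not in _STAGE_FN:
        raise ValueError(f"unknown stage {stage!r}")
    inputs, outputs = _STAGE_IO[stage]
    if stage == "detect" and cfg.genome_fasta:
        inputs = ()
    run._stage(stage, lambda: _STAGE_FN[stage](run), inputs, outputs)
    return run.outdir


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages in order; writes the fully resolved config next
    to the outputs.  Raises StageError naming the failing stage."""
    run = Run(cfg)
    cfg.to_yaml(run.path("config.resolved.yaml"))
    stages = list(STAGES)
    if cfg.genome_fasta:
        stages.remove("simulate")
    for stage in stages:
        run_stage(cfg, stage)
    return run.outdir
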