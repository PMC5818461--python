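# crckit

Discovery, classification, census and dating of **centromeric LTR
retrotransposons** (the CRM/chromovirus lineage of the *Gypsy*
superfamily) in genome assemblies — together with a planted-truth genome
simulator that makes every step of the pipeline testable end to end.

Plant centromeres are typically built from satellite arrays invaded by a
specific *Gypsy* lineage of "centromeric retrotransposons" carrying
heterochromatin-targeting signals (a chromodomain at the integrase
C-terminus, or a distinct CR motif near the 3′ LTR).  Annotating these
elements requires a chain of classical analyses: de novo structural
detection of paired-LTR elements, protein-domain annotation, family
definition from a bootstrapped reverse-transcriptase (RT) phylogeny,
genome-wide copy census at coverage/identity thresholds, insertion dating
from LTR–LTR divergence, and density/composition profiling of candidate
centromeric regions.  `crckit` implements that chain as a reusable,
deterministic pipeline for anyone studying repeat-dense plant genomes,
and validates it on synthetic chromosomes where the truth is known.

## The core quantities

* **Structural detection.**  An LTR retrotransposon is found as a pair of
  similar direct repeats (the LTRs, here 100–2,500 bp) spaced compatibly
  with an element of 1–18 kb, polished to the 5′-TG…CA-3′ termini and an
  exact 4–6 bp target-site duplication (TSD), and oriented by its primer
  binding site (PBS) and polypurine tract (PPT).
* **Superfamily and family.**  Coding-domain order separates *Gypsy*
  (…RT–RH–INT…) from *Copia* (…INT–RT–RH…).  Families are maximal
  well-supported clades (neighbor-joining tree of RT domains, 1,000
  bootstrap replicates, support ≥ 70%) whose members share ≥ 80% RT
  nucleotide identity.  Non-autonomous derivatives are typed TRIM
  (non-coding, ≤ 1.5 kb, LTRs ≤ 250 bp), LARD (non-coding, ≥ 4 kb) or
  TR-GAG (GAG retained, POL lost).
* **Copy census.**  Copies of a family representative are *complete* at
  > 80% coverage **and** > 80% identity, *fragments* at > 10% coverage and
  > 80% identity (strict inequalities).
* **Insertion age.**  The two LTRs are identical at insertion; their
  Kimura two-parameter distance K = −½·ln((1−2P−Q)·√(1−2Q)) over
  transition (P) and transversion (Q) fractions gives
  **T = K / (2r)** with r = 1.3×10⁻⁸ substitutions · site⁻¹ · year⁻¹.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/02_detect_and_score.py
```

prints, for the default seed:

```
wrote 2,314,695 bp genome with 40 complete elements and 20 decoys across 10 families
detected 40 elements: recall 1.0, precision 1.0 at 5-bp boundary tolerance
```

i.e. every planted complete element (ages 0–2 Mya) was recovered with
boundaries within 5 bp of the truth, and none of the 20 LTR-less decoys
produced a false call.  Continuing the chain:

```bash
python analysis/03_classify_families.py
python analysis/04_census_and_dating.py
python analysis/05_centromere_report.py
```

```
89 RT domains -> 10 groups, membership accuracy 1.000
within-group identity 89-96%, between-group representatives 51-55%
...
dating recovery: {"0.5My": {"median_estimate_years": 510771, "recovery_rel_error": 0.0215}, ...}
centromere composition: 90.0% TE, 35.6% CRC, dominant family 21.2%
satellite search: 0 arrays in the element-only centromere; planted array recovered with period error 0 bp
```

The ten planted families are recovered exactly across three genomes
(within-family RT identity ~90%, between-family ~55%); median K2P age
estimates land within 2–4% of the planted ages at every age point; and
the tandem-satellite scan stays empty on an element-only centromere while
finding a planted 170-bp array at its exact period.

The same stages are available as a CLI (`crc simulate|detect|annotate|
classify|census|date|density|report|run`, with `--config`, `--seed`,
`--outdir`); two runs with the same config and seed produce byte-identical
outputs.

## Layout

* `src/crckit/` — the library: `simulate`/`templates`/`scenarios`
  (planted-truth genomes), `detect` (structural search), `domains`
  (translated domain scan), `classify`/`njtree` (families, NJ, bootstrap),
  `census` (copies, K2P dating, density, satellites), `io`, `config`,
  `pipeline`, `cli`.
* `analysis/` — numbered narrative drivers over the library.
* `tests/` — unit, property and end-to-end acceptance tests.
* `docs/methods.md` — models, parameter choices and limitations.
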