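# genevol

Genome-evolution summaries for plant genome projects, built around the
analyses that accompany a chromosome-scale assembly such as the purpleblow
maple (*Acer truncatum*) genome: dating whole-genome duplications from the
paranome's 4DTv distribution, dating LTR retrotransposon insertions from
LTR divergence, locating centromeres from satellite tandem repeats,
calling gene-family members (KCS, LEA) with rule-based homology and
Pfam-domain filters, and computing the standard expression and assembly
summaries (RPKM, fold changes, 2^−ΔΔCt, N50, completeness ratios).

Every stage is exercisable end-to-end on synthetic data with recorded
ground truth, so the whole pipeline is testable without any downloads.

## The statistics at the core

* **4DTv** — for a codon-aligned paralog pair, the fraction of
  fourfold-degenerate third-codon sites differing by a transversion,
  corrected for multiple hits with the HKY-consistent transversion
  distance d = −2·πR·πY·ln(1 − Q/(2·πR·πY)) (equal frequencies:
  −½·ln(1−2Q)).  Peaks of the paranome distribution mark whole-genome
  duplications.
* **LTR insertion age** — T = K/(2r), with K the Jukes–Cantor distance
  −(3/4)·ln(1 − (4/3)p) between an element's two LTRs and
  r = 1.3×10⁻⁸ substitutions/site/year.
* **Centromeric satellite** — tandem-repeat monomers clustered by
  rotation- and strand-invariant identity; the cluster covering the most
  bases is the base repeat, and its genomic density peak in 300-kb
  windows locates each centromere.
* **Gene-family screen** — a gene is a member iff some hit passes
  E ≤ 1e−5, identity ≥ 50%, query coverage ≥ 50% *and* the gene carries
  all diagnostic Pfam domains of the query; tandem arrays are chains of
  neighbouring members.
* **Expression** — RPKM = counts·10⁹/(library size · gene length);
  log10(RPKM+1) with RPKM ≤ 1 floored to 0; stage fold changes on
  replicate-averaged RPKM; qPCR relative expression 2^−ΔΔCt.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Simulate 200 LTR elements that all inserted 1.5 Mya, then date them:

```sh
genevol simulate ltr-cohort --n 200 --age-mya 1.5 --seed 1 --out ltrs.fa
genevol ltr-age --pairs ltrs.fa --out ages.tsv
```

which prints

```
LTR burst peak: 1.38 Mya
```

and writes per-element rows to `ages.tsv` plus a summary `ages.json`:

```
element_id  p         K         T_years    T_mya   status
elt0000     0.035000  0.035843  1378576.8  1.3786  ok
elt0001     0.037000  0.037944  1459378.4  1.4594  ok
...
```

`p` is the mismatch fraction between the element's two LTRs, `K` the
Jukes–Cantor distance and `T` the implied insertion age; the cohort mean
age recovers the planted 1.5 Mya to within sampling error, and the modal
0.25-Mya bin (midpoint 1.38) contains the truth.

The full demo generates every fixture, runs every stage and verifies each
estimate against the recorded truth:

```sh
genevol run-demo --seed 42 --outdir demo/
# -> all checks passed (6 checks)
```

`demo/report.json` lists, per stage, the estimate, the truth and the
pass/fail verdict; reruns with the same seed are byte-identical.

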