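# ltrkit

Mining, dating and quantification of LTR retrotransposon (LTR-RTE)
families, plus retrotransposon-based marker diversity analysis — the
computational half of a typical plant transposable-element
characterization study (the motivating system is *Eucalyptus*), with a
synthetic-data generator so every stage is testable end to end without a
reference genome or wet-lab data.

## What it does

**Copy mining** (`ltrkit.mining`). Given a genome and reference
full-length elements, copies are located by exact k-mer seeding and
semi-global affine alignment (match +1, mismatch −1, gap open −3,
extend −1), on both strands. A copy is *full length* when it covers
≥ 80 % of the reference at > 80 % identity and, after ±3 bp boundary
refinement, carries the canonical `5'TG..CA3'` LTR termini. Target-site
duplications (4–6 bp exact flank repeats) and poly-purine tracts are
detected and reported.

**Dating and classification** (`ltrkit.evolution`). The two LTRs of an
element are identical at integration, so their divergence clocks the
insertion. For an intact copy (two LTRs + TSD) the LTR pair is aligned
globally and the Kimura two-parameter distance

    K = -1/2 ln[(1 - 2P - Q) sqrt(1 - 2Q)]

(P transitions, Q transversions, pairwise deletion of gap columns)
converts to an age **T = K / 2r** with r = 1.5 × 10⁻⁸
substitutions·site⁻¹·year⁻¹. Families follow the 80-80-80 rule —
single-linkage components of LTR pairs with ≥ 80 % identity over ≥ 80 %
of the shorter LTR — named `RLC`/`RLG` (Copia/Gypsy) + host code +
lineage + index, e.g. `RLC_egAle_1`. Per-family LTR diversity (Pi) is
the mean pairwise p-distance.

**qPCR quantification** (`ltrkit.qpcr`). Standard curves regress mean Ct
on log₁₀(concentration); the slope y gives the amplification efficiency
E = (10^(−1/y) − 1) × 100 and the per-cycle fold 1 + E/100 (slope
−3.3219 ⇔ E = 100 %, fold 2). Relative copy number uses 2^(−ΔΔCt)
against a single-copy reference gene; relative expression uses the
efficiency-corrected (1+E)^(−ΔΔCt) with the lowest-expression sample as
calibrator (RQ = 1). Normalizer stability is geNorm's M; group contrasts
use one-way ANOVA gated Fisher's LSD.

**Dominant markers** (`ltrkit.markers`). IRAP/REMAP band matrices are
compared with the Jaccard coefficient GSj = a/(a+b+c) (double absences
uninformative) and clustered by UPGMA into an ultrametric dendrogram
(Newick output), with per-species × primer polymorphism summaries.

**Simulation** (`ltrkit.simulate`). Background genomes with planted
copies of known family, age, TSD and termini (full K2P Markov process
with back-mutations — exactly the model the estimator inverts), Ct
tables with configurable efficiency and Gaussian noise, and
species-structured binary marker matrices.

## Worked example

```python
import ltrkit as lk

config = lk.SimulationConfig(seed=4, genome_length=120_000, tsd_length=5)
ref = lk.make_reference_element("RLC_egAle_1", superfamily="Copia", lineage="Ale",
                                ltr_length=400, internal_length=1400, seed=8)
genome, truths = lk.build_synthetic_genome(config, [ref], copies_per_family=4,
                                           ages=[0.0, 1e6, 2e6, 3e6])
copies = lk.find_copies(genome, ref)
print(f"{'copy':<18}{'status':<13}{'identity':>9}{'coverage':>9}  {'TSD':<7}{'age (Mya)':>10}")
for c in copies:
    age = lk.date_element(c, genome).T / 1e6 if c.is_intact else float("nan")
    print(f"{c.copy_id:<18}{c.status:<13}{c.identity:>9.3f}{c.coverage:>9.3f}  "
          f"{c.tsd or '-':<7}{age:>10.2f}")
```

Output:

```
copy              status        identity coverage  TSD     age (Mya)
genome_copy_1     full_length      1.000    1.000  CTTGA        0.00
genome_copy_2     full_length      0.988    1.000  GATGA        1.02
genome_copy_3     full_length      0.967    1.000  TGATG        2.36
genome_copy_4     full_length      0.952    1.000  GAACA        2.93
```

All four planted copies (true ages 0, 1, 2, 3 Mya) are recovered as full
length with their exact 5-bp TSDs; the age-0 copy has byte-identical
LTRs (K = 0, T = 0 exactly) and the older copies date close to truth,
with per-copy scatter set by LTR length (400 bp here: sd(K) ≈ √(K/L)).

The same pipeline is scriptable from the shell:

```bash
ltrkit simulate genome --seed 5 --families 3 --out-fasta g.fa --out-gff truth.gff3 \
    --out-refs-fasta refs.fa --out-refs-table refs.tsv
ltrkit mine --genome g.fa --refs refs.fa --refs-table refs.tsv --out-tsv copies.tsv
ltrkit qpcr curve --ct dilution.tsv
ltrkit markers tree --matrix bands.tsv --out tree.nwk
```

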