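# crmsearch

Discriminative discovery of compact *cis*-regulatory modules (CRMs) in
small promoter sets.

## The problem

Given a handful of promoter fragments that drive a phenotype of interest
(the **positive set**, e.g. 13 bacterial promoters active exclusively in
tumor tissue) and a larger collection that does not (the **negative set**,
e.g. 115 inactive fragments from the same promoter-trap library), which
*combination* of sequence features explains the activity — and can be cut
out and tested in the lab?  Single-motif statistics fail at this scale:
every motif-discovery program adds candidates, and the true discovery rate
of any one method is only ~5–10%.  `crmsearch` instead integrates
heterogeneous features — known and de novo DNA motifs, transcription start
site (TSS) predictions, duplex-destabilization (SIDD) tracks, AT/GC-rich
regions, poly-A tracts, repeats — and searches for *sets* of features that
are jointly specific and physically compact.

## The method

Every feature type φ places located occurrences on sequences.  With
**coverage** `C^S_φ` = fraction of sequences in set S carrying ≥ 1
occurrence and **frequency** `F^S_φ` = occurrences per bp:

1. **Discriminative PWM thresholds.**  Each position weight matrix gets an
   individual min-max–normalized score threshold maximizing `C⁺/C⁻`
   subject to the boundary conditions `C⁺ ≥ 0.75`, `C⁻ ≤ 0.5` and
   `F⁺/F⁻ ≥ 2`; matrices with no qualifying threshold are excluded.
   Accepted thresholds are relaxed by 0.05 before the combinatorial stage
   so weaker occurrences are kept.
2. **Modules.**  A module Φ = (φ₁,…,φ_k) covers a sequence when all
   members occur on it; its **support sequence** is the shortest interval
   containing one full occurrence of every member (smallest-range-over-k-
   lists).  **Module overlap** is the summed bp intersection of two
   modules' supports across the positive set.
3. **Genetic algorithm.**  Seeded with all feature pairs, mutated by
   exchange / add / delete / merge, elitist truncation on the fitness
   `C⁺_Φ / C⁻_Φ` (half-count `1/(2N⁻)` when `C⁻ = 0`).  Every selection
   interval the K-subset of the top candidate pool minimizing total
   pairwise support overlap is selected:

       C⁺_Φi / C⁻_Φi → max   (i = 1…K)
       Σ_{i≠j} |M_Φi,+ ∩ M_Φj,+| → min

   The search stops when the selected K-set is unchanged for a configured
   number of consecutive selections.  Minimizing mutual overlap favors
   *compact* modules — the property that lets a module be excised and
   cloned in one fragment — and suppresses near-duplicate hypotheses.

Because real promoter-trap datasets of this kind are not distributable, a
first-class synthetic generator (`crmsearch.simulate`) reproduces their
statistical structure (fragment lengths 640 ± 232 bp truncated at 100 bp,
set-specific GC content, planted module in 80% of positives, partial
modules in 30% of negatives, 20 decoy feature types) so every stage is
testable end to end.

## Worked example

```sh
crmsearch simulate --seed 1 --out-dir fixture
# wrote 13+115 sequences and 5218 ground-truth instances to fixture
crmsearch search --pos fixture/positive.fasta --neg fixture/negative.fasta \
    --track fixture/ground_truth.gff3 --k 5 --runs 1 --seed 1 --out-dir search_out
```

```
                                      features    C+ p-value    C- fitness  rank(C-)
module
1                planted_1+planted_2+planted_3  0.77          0.00     177         1
2       decoy_07+planted_1+planted_2+planted_3  0.77          0.00     177         2
3       decoy_08+planted_1+planted_2+planted_3  0.77          0.00     177         3
4       decoy_12+planted_1+planted_2+planted_3  0.77          0.00     177         4
5       decoy_13+planted_1+planted_2+planted_3  0.77          0.00     177         5
5 modules from 1 runs, 5 unique; artifacts in search_out
```

Module 1 is the exact planted feature set: it occurs on 10/13 positives
(C⁺ = 0.77), never on a negative (C⁻ = 0), so its fitness is
0.77/(1/230) ≈ 177.  Modules 2–5 are supersets padded with ubiquitous
decoys — recognizably redundant from the emitted Jaccard similarity
matrices (`search_out/modules.json`), mirroring the manual "OR-logic"
grouping step that follows a real run.  `search_out/supports.gff3` holds
the support intervals to cut and clone.

The same pipeline is available as a library; see
`crmsearch.benchmark.run_recovery_benchmark` for the complete
generate → screen → relax → rescan → search flow in one call.

## Layout

| module | contents |
|---|---|
| `crmsearch.core` | sequences, features, coverage/frequency, supports, overlap |
| `crmsearch.pwm` | PFM parsing (JASPAR/TRANSFAC), log-odds PWMs, scanning, discriminative thresholds |
| `crmsearch.detectors` | AT/GC-rich regions, poly-A tracts, exact repeats, track import, screening |
| `crmsearch.search` | genetic algorithm, K-module min-overlap selection, p-values, multi-run driver |
| `crmsearch.simulate` | synthetic promoter sets with planted modules; genome fragmentation |
| `crmsearch.benchmark` | the end-to-end recovery benchmark |
| `crmsearch.io`, `crmsearch.report`, `crmsearch.cli` | formats, tables, command line |

See `docs/methods.md` for the model's assumptions, parameter defaults and
known limitations.
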