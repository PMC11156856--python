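# paracis

Cis-regulatory analysis of paralogous gene families.

Recently expanded gene families — the motivating case is the murine Ly49
cluster of natural-killer-cell receptors — consist of near-identical loci
whose promoters and enhancers diverged from a common ancestor. Analyzing
their regulation breaks most standard pipelines twice over: short reads
multimap across the paralogs and get discarded by MAPQ filters, and signal
on different paralogs cannot be compared because each locus has its own
coordinates. `paracis` provides the bespoke computational steps such a study
needs, each implemented against synthetic data with known ground truth:

- **`consensus`** — majority-rule consensus from a paralog MSA (threshold
  0.5, gap-consensus columns dropped), per-paralog coordinate maps, per-bp
  signal projection onto consensus coordinates, fixed-sum normalization with
  a computed noise floor (`2nL/G`; 1.5/bp for a 30 M-pair 2×75 bp library on
  a 3 Gbp genome).
- **`rescue`** — multimapper rescue by normalized alignment score
  nAS = AS/read_length: drop placements with nAS < −0.1, assign the unique
  best survivor or all tied best placements, remove target placements that
  map strictly better elsewhere, merge with primary-pipeline reads. Includes
  an exhaustive dynamic-programming oracle for validation.
- **`atac`** — Tn5 insertion events → 150 bp pseudo reads, depth-normalized
  pileups, MAP-by-sample count matrices with median-reference
  normalization.
- **`cage`** — architecture filtering (TLEN > 10 kb, soft clip > 3 bp, any
  mismatch), windowed UMI deduplication, power-law normalization
  (α = 1.2, T = 10⁶), two-step distclu peak calling (loose ∩ strict,
  loose boundaries), cap-signature filter (> 70% unencoded-G reads),
  CAGE–ATAC log2 Pearson correlation.
- **`coexpr`** — binarized cell×gene matrices, per-pair 2×2 tables,
  odds ratio (d/c)/(b/a), exact two-sided Fisher tests, Benjamini–Hochberg
  FDR, mean-OR / max-FDR combination across replicates.
- **`hic`** — vanilla-coverage normalization, hotspot vs neighborhood mean
  contact frequencies, distance- (± 5 kb) and coverage-matched background
  selection (k = 10), aggregate pair profiles, Welch enrichment tests.
- **`conserved`** — conserved elements (≥ 10 bp columns at ≥ 90% identity),
  PWM scanning with exact DP-computed p-values (cutoff 0.01), VISTA-style
  100 bp sliding-window identity (> 70% highlighting), direct/inverted
  homology search (≥ 100 bp at ≥ 60% identity).
- **`synth`** — seeded generators for every input above, shipping their
  ground truth: paralog families with mutation logs and constructively
  built true alignments, planted conserved elements, enriched Tn5
  insertions, scored multireads, cell matrices with planted odds ratios,
  and decaying contact matrices with planted hotspots.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Generate a paralog family carrying a shared 120 bp regulatory element,
simulate accessibility data enriched 8× at that element, and view the signal
on consensus coordinates; then rescue multimapping reads and recover a
planted co-expression odds ratio:

```python
import numpy as np
from collections import Counter
from paracis import synth, consensus, coexpr, rescue

cfg = synth.SimulationConfig(seed=42, n_paralogs=8, ancestor_length=800,
                             substitution_rate=0.03, indel_rate=0.0)
fam = synth.generate_paralog_family(cfg)
fam = synth.plant_conserved_element(fam, "ACGTTGCAAC" * 12,
                                    carriers=fam.names, rng=1)
element = fam.planted_elements[0]
sim = synth.simulate_insertions(fam, synth.SimulationConfig(seed=42, depth=3000),
                                enrichment_map={element.name: 8.0})

msa = fam.paralog_msa
cons = consensus.build_consensus(msa)
cmap = consensus.build_coordinate_map(msa, cons)
tracks = {}
for name in fam.names:
    events = sim.events[name][0]
    track = np.bincount(events, minlength=len(fam.sequence(name))).astype(float)
    tracks[name] = consensus.project_signal(track, cmap, name)
stacked = consensus.normalize_and_stack(tracks)

s, t = element.ancestor_interval
inside = stacked.iloc[:, s:t].to_numpy().mean()
outside = np.concatenate([stacked.iloc[:, :s].to_numpy(),
                          stacked.iloc[:, t:].to_numpy()], axis=1).mean()
print(f"consensus length: {len(cons)}")
print(f"mean pileup signal inside planted element:  {inside:.1f}")
print(f"mean pileup signal outside planted element: {outside:.1f}")

mr = synth.simulate_multireads(fam, read_length=75, n_reads=500,
                               seed=7, error_rate=0.01)
decisions = [rescue.rescue_assign(a) for a in mr.alignments]
print("rescue decisions:", dict(Counter(d.reason.value for d in decisions)))

m = synth.simulate_cell_matrix(5000,
                               {"Ly49a": 0.3, "Ly49g": 0.3, "Ly49i": 0.2},
                               [("Ly49a", "Ly49g", 6.0)], seed=3)
res = coexpr.pairwise_odds_ratios(m)
row = res[(res.gene_x == "Ly49a") & (res.gene_y == "Ly49g")].iloc[0]
print(f"planted pair OR = {row.odds_ratio:.2f} (target 6), FDR = {row.fdr:.2e}")
```

Output:

```
consensus length: 920
mean pileup signal inside planted element:  47.1
mean pileup signal outside planted element: 7.2
rescue decisions: {'discarded_low_score': 84, 'multi_equal': 59, 'unique_best': 357}
planted pair OR = 6.07 (target 6), FDR = 5.39e-158
```

The planted element stands out ~6.5-fold on the stacked pileup (noise floor
1.5/bp included); most 75 bp reads resolve uniquely, a fraction tie across
paralogs and are assigned jointly, reads with more than one error fall
below the nAS cutoff and are discarded; the planted odds ratio of 6 is
recovered at overwhelming significance.

A thin CLI mirrors the file-facing workflows:

```sh
paracis synth family --seed 4 --out fam/
paracis pileup --msa fam/true_msa.fa --tracks tracks/ --out out/
paracis rescue --alignments aln.tsv --out counts.tsv
paracis coexpr --matrix s1 --matrix s2 --out heatmap.tsv
paracis hic normalize --contacts contacts.tsv --out normalized.tsv
paracis conserve runs --msa msa.fa --out elements.bed
```

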