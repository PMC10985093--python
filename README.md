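# loopshift

Integrative analysis of how a point-mutation condition changes a chromatin
architectural protein's genome-wide binding and the 3D genome it organizes —
modeled on the CTCF / mESC setting, where an O-GlcNAcylation-deficient CTCF
(MUT) is compared against wild type (WT). The package implements, as one
tested pipeline over seeded synthetic data with planted ground truth:

- **Spike-in differential ChIP-seq.** Exogenous reference chromatin gives
  per-sample scale factors `f_i ∝ 1/spike_total_i` (rescaled to mean 1), so a
  *global* binding shift — invisible to per-library total-count scaling — is
  measurable. Differential binding per peak uses a negative-binomial Wald
  test: method-of-moments dispersions on within-group normalized counts,
  shrunk toward the trimmed ensemble mean; `z = log2FC / SE` with the SE from
  the delta method on the NB variance `μ + αμ²`; Benjamini–Hochberg FDR.
- **Hi-C core.** Contact matrices from pair records; ICE balancing
  (`balanced(i,j) = count/(b_i·b_j)` with MAD-based low-coverage masking);
  distance-decay expected; relative contact probability; A/B compartment
  scores as the leading eigenvector of the O/E correlation matrix at 250 kb,
  sign-oriented by promoter density; stratum-adjusted correlation (SCC) for
  replicate reproducibility.
- **Loops and domains.** Donut-filter loop calling: each pixel versus four
  local expected models (donut, lower-left, horizontal, vertical stripes),
  Poisson p-value against the most conservative, BH within distance strata at
  FDR 0.1, fold filters 1.75/1.75/1.5/1.5, 8-connected cluster merging.
  Insulation-minima contact domains; *loop domains* (domains whose endpoints
  form a loop); cross-condition merging by both-anchor overlap; differential
  loops via the shared NB test on loop-pixel counts; APA
  (observed/expected submatrix average; score = center over lower-left
  corner block).
- **Integration.** CTCF-related loops (peaks on both anchors); E-E/E-P/P-P/I-I
  typing with promoter > enhancer > insulator anchor precedence; permutation
  enrichment of binding signal on target anchors (uniform within-chromosome
  shuffles, one-tailed normal p per `z = (obs − μ₀)/σ₀`); overlap fraction of
  strengthened E-P loops with enhanced peaks; expression concordance of their
  target genes with a one-tailed chi-square
  `χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`; and XIC stoichiometry of a PTM
  from modified/unmodified peptide peak areas.
- **Synthetic data.** A seeded generator plants the full structure the
  analysis is meant to find: a global binding factor plus a 2× enhanced peak
  subset with spike-in truth, distance-decaying matrices with checkerboard
  compartments, block domains, focal loops strengthened/weakened 2×/0.5× in
  MUT, and expression fold changes coupled to strengthened-loop anchors.

## Worked example

The whole study runs from one seed, as a library call or the CLI
(`loopshift run --seed 1 --outdir out/`). The numbered drivers under
`analysis/` run it stage by stage:

```bash
python analysis/01_simulate_study.py
python analysis/04_loops_domains_apa.py
python analysis/05_integration.py
```

prints (seed 1):

```
loops called: WT 57, MUT 51, union 70
differential loops: 9 strengthened, 5 weakened
loop domains: WT 6, MUT 6, merged 7 (2 enhanced, 1 weakened)
APA on strengthened loops: WT 2.83 vs MUT 4.71 (paired t=-11.05, p=4e-06)
planted-loop recovery: all 0.90, strengthened 1.00
...
CTCF-related loops: 65
strengthened E-P: 8, weakened E-P: 3
binding enrichment on strengthened E-P anchors: z=10.10, one-tailed normal p=2.63e-24
strengthened E-P loops with enhanced peaks: 100.00% (8 loops)
target genes: 96; fraction up-regulated (DE rule): 75.00%; fraction with log2FC>0: 84.38%
one-tailed chi-square vs background: chi2=58.23, p=1.17e-14
```

Reading: all 9 planted strengthened loops are re-discovered and re-labeled
strengthened; APA confirms they gain contact strength in MUT; CTCF binding
concentrates on their anchors far beyond shuffled peaks; and the genes whose
promoters sit on those anchors are predominantly up-regulated — the planted
binding→structure→expression chain, recovered end to end. The
`report.json` emitted by `loopshift run` collects the same quantities plus
recovery-vs-truth metrics and is byte-identical for identical seeds.

## Layout

- `src/loopshift/` — the library: `intervals` (BED/BEDPE/bedGraph I/O and
  interval arithmetic), `counts` (normalization + NB testing), `hic`
  (matrices, ICE, compartments, SCC), `loops` (loop/domain calling, APA),
  `integrate` (typing, permutation, concordance, stoichiometry),
  `simulate` (generator), `pipeline` (orchestration), `cli`.
- `analysis/` — numbered narrative drivers.
- `tests/` — unit, property, and acceptance suites.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
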