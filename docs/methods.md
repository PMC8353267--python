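# Methods

## Scope and data model

`srmkit` models the analysis path of a multiplexed SRM experiment from
assay coordinates to differential protein abundance. It deliberately
starts *after* chromatographic peak integration: the unit record is one
integrated transition peak (area, transition-specific background level,
S/N, observed RT) per run, as exported by peak-picking software. Peak
integration, interference detection beyond the light/heavy fragment
dot-product check, collision-energy optimisation and absolute (fmol)
quantification are out of scope.

## Assay design

Masses are monoisotopic throughout (proton 1.007276 Da, H₂O
18.010565 Da), appropriate for a triple quadrupole operated at unit
resolution on monoisotopic targets. Digestion follows the trypsin rule
— cleave C-terminal to K/R, suppressed before proline, zero missed
cleavages by default — which also subsumes LysC in a dual LysC/trypsin
protocol, since that combination converges to fully tryptic peptides.
Cysteines carry fixed carbamidomethyl (+57.021464 Da, iodoacetamide
alkylation); no variable modifications are modelled, matching the use
of unmodified synthetic reference peptides.

Heavy reference peptides are C-terminally labelled (K +8.014199 Da,
R +10.008269 Da), the standard choice for tryptic peptides: the label
shifts the precursor and the full y-ion series while b ions stay
label-invariant, which is what makes the light/heavy fragment
comparison diagnostic. Candidate peptides are restricted to 7–25
residues (SRM detectability convention) and must end in K/R so a heavy
twin exists. A peptide is proteotypic iff it occurs in exactly one
entry of the reference proteome; a peptide absent from the proteome is
*not* proteotypic, since specificity is only defined with respect to
that reference. Targets whose digest yields no proteotypic peptide are
excluded with that reason rather than silently dropped.

Fragment candidates are singly/doubly charged b/y ions; during
development the 20 best-ranked fragments per precursor charge (2+ and
3+) are enumerated, and the final panel attaches each peptide's top
4–10 transitions at the lower precursor charge. Ranks come from a
spectral-library table when available; otherwise a deterministic
fallback ranking is used (y before b, longer fragment first, 1+ before
2+ — the usual intensity ordering of tryptic peptides at low collision
energy). Rank ties break by (y before b, lower index, lower fragment
charge) purely for determinism. Whether published "top-20" selections
pooled both precursor charges is generally ambiguous; enumeration here
is per precursor charge.

The shipped ten-marker panel uses a seed-generated **synthetic**
proteome (real marker gene names, synthetic sequences assembled from
designed tryptic peptides, plus decoys and a NANOG-like paralogue pair
whose shared peptides exercise the proteotypicity exclusion). Its m/z
coordinates therefore do not correspond to the human proteins; it
exists so that design → schedule → simulate → quantify runs with no
external database. The shipped panel carries 6 transitions per peptide
(within the 4–10 rule); with 4 peptides per marker and heavy twins that
keeps worst-case scheduled concurrency ≈120, i.e. a 1.2 s cycle at
10 ms dwell, inside the 1.7 s budget.

## Scheduling

iRT→RT calibration is an ordinary least-squares line (≥2 distinct iRT
values required); the residual SD is reported so window widths can be
sanity-checked against calibration scatter. Windows are centred on the
predicted RT with fixed width (default 4 min) and **clipped** — not
shifted — at the gradient boundaries, preserving centre ordering;
light/heavy twins share one window because they co-elute by
construction. Concurrency uses the half-open convention [start, end):
touching windows do not overlap, avoiding double-counting at shared
endpoints. The effective cycle time is
`max_concurrency × (dwell + interscan_overhead)`; the overhead default
is 0 s because a 170-transition concurrency at 10 ms dwell filling a
1.7 s cycle implies negligible per-transition overhead on this
instrument class, but it is configurable. Method exports report light,
heavy and total transition counts separately, since published totals
are ambiguous about whether heavy twins are included.

## Quantification

Thresholds use strict inequalities at both boundaries: a peak group is
retained iff its top transition has S/N **> 3**, and imputation applies
iff area **<** background (an area equal to its background is kept).
The "top" transition is the light transition with the highest peak area
within the peak group in that run. S/N is consumed from the input, not
recomputed. Every input row lands in exactly one of retained/rejected —
no silent drops — and the below-background rule (area → background/3)
is idempotent.

Quantification uses light-label areas; heavy areas serve co-elution
verification (ΔRT ≤ 0.5 min and normalised fragment-area dot product
≥ 0.9 by default; the dot product is scale-invariant, so spike-in level
does not matter). A `ratio_to_heavy` mode that quantifies
log2(light/heavy) instead is provided but off by default, documented as
the alternative reading where reference-normalised quantification is
preferred.

Detection tiers per protein × condition: *quantifiable* = ≥2 distinct
peptides each detected (surviving the S/N filter) in ≥3 replicates;
*detectable* = at least one peptide detected anywhere but the
quantifiable rule unmet (a single detection in a single replicate
suffices for this tier — the stricter ≥3-replicate reading is possible
but not adopted); *not_detected* otherwise. A comparison is attempted
whenever a protein is quantifiable on either side (condition or
control).

The group comparison fits transition-level log2 abundances with
condition and feature (peptide × charge × fragment) fixed effects and a
run random intercept, by REML. The contrast df is the between-run df
(n_runs − 2): for the balanced two-group contrast the run level is the
effective unit of replication and the Satterthwaite df collapses to
this value, so the simpler rule is used directly. When the run-variance
estimate collapses to zero, when the residual variance estimate
vanishes (ill-conditioned GLS weighting), or with a single feature, the
model degrades to the fixed-effects two-way layout with residual df —
the point estimate is unchanged on balanced data, only SE/df move.
BH adjustment is applied across proteins within one condition-versus-
control comparison (not pooled over conditions), mirroring
per-comparison reporting. Condition summaries show the median of
replicate-level protein abundances with a t-interval about the mean
(n ≥ 2; a single replicate yields the median only).

## qPCR analysis

dCt = mean(Ct_hk1, Ct_hk2) − Ct_target, so induction (fewer cycles)
plots upward; the sign is configurable since the opposite convention is
also common. dCt is invariant to swapping the housekeeping genes.
Profiles are z-scaled with the *sample* SD (ddof = 1); constant series
are an error rather than 0/0. Pearson significance uses the exact
two-sided t transform with no multiplicity correction across
correlogram cells (per-cell α = 0.05). Pairwise Pearson r is affine-
invariant, so correlating raw or z-scaled series is equivalent;
z-scaling matters only for plotting different targets on one axis.
Co-expression clustering is agglomerative with Euclidean distance and
average linkage (a conventional choice for dCt heatmaps; the method is
a parameter, not a contract), with profiles sorted by target id first
so the tree is input-order invariant.

## Synthetic data

The generator emulates the *statistical structure* of a
differentiation time-course transition report — the same structure the
quantification model assumes:

    log2 area = T_p(time) + β_q + log2 φ_f + u_r + ε

with per-protein piecewise-linear log2 trajectories T_p (defaults:
neuronal markers rising by +1.7 to +3.0 log2 units over 28 days, NSC
markers falling, S100B dip-then-rise, OCT4 below background, GFAP/GALC/
OLIG1 near the detection limit), peptide digestion-efficiency offsets
β_q ~ N(0, 0.5²), fixed Dirichlet fragment fractions φ summing to 1 per
peptide, run effects u_r ~ N(0, 0.1²) shared by all proteins in a run,
and noise ε ~ N(0, 0.2²). Four biological replicates per condition
(three for qPCR) match common practice. Backgrounds are per-transition
log-normal (log2 mean 8, SD 0.7); areas below background are reported
as-is so the imputation path is exercised. Heavy spike-ins are constant
(log2 16) with the peptide's fragment profile and shared run effect.
S/N is generated as area/background — a declared proxy for a
peak-picker's estimate. Ct values couple negatively to protein level
(ct = 38 − 1.0·T_p + N(0, 0.25²)), housekeeping Cts are constant plus
noise, so higher protein ⇒ lower Ct ⇒ higher dCt.

What the simulator does **not** reproduce: chromatographic trace
shapes, transition interference, isotope effects, digestion
variability that differs between conditions, batch effects beyond one
run random effect, and any real biological effect sizes. Passing tests
therefore demonstrate correctness of the *rules and estimators* under
the assumed error model, not performance on real instrument data.

## Verification problem sizes

The acceptance computations use: 100 random window sets for the
concurrency sweep-versus-brute-force check; 500 random p-vectors for
the BH step-up oracle; 1000 random peptides (2–25 residues, random
charges, heavy twins where tryptic) against an independent
elemental-composition mass oracle at 1e-4 Th (b/y complementarity at
1e-6); 200 simulated proteins (2 peptides × 3 transitions × 4
runs/group) for CI coverage and bias; 500 null proteins in BH families
of 20 for false-positive calibration; and one full default time-course
(10 proteins × 5 conditions × 4 replicates, 9600 report rows) for
end-to-end fold-change recovery. These sizes give stable estimates in
well under a minute per block on one core.

On bias metrics: across simulated proteins the reported
`log2fc_median_bias` is the magnitude of the *median signed error* —
the systematic component, ≈0.01 log2 units. The median *absolute* error
(also reported) is ≈0.06, which is simply the sampling noise implied by
the design: with σ_run = 0.1 and 4 runs per group the contrast SE is
bounded below by √(2σ²_run/4) ≈ 0.07 regardless of how many transitions
are measured.

## Known limitations

- Fragment intensities and iRTs are inputs, never predicted from
  sequence; without a spectral library the fallback ranking is a
  heuristic.
- The mixed model assumes equal feature variance and no
  feature × condition interaction; outlier transitions are not
  down-weighted.
- The Satterthwaite-equivalent df shortcut (n_runs − 2) is exact for
  balanced two-group contrasts but approximate under missingness.
- The shipped panel is synthetic; for real assays, supply target and
  proteome FASTA plus a spectral-library rank table.
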