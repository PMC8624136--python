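# Methods

## Scope and data model

The package analyses plot-level canopy reflectance spectra and grain
yields from a salt-tolerance field trial laid out as a randomized
complete block design with a split-plot arrangement: salinity treatment
(control vs saline irrigation) in main plots, genotype in subplots,
with blocks (replicates) and possibly several years. Reflectance is
stored as a fraction in [0, 1] on an integer wavelength grid; inputs on
a percent scale (values > 1.5) are divided by 100 with a warning.

The canonical grid is 350–2500 nm at 1 nm: 2151 samples spanning 2150
one-nm bands. "Band count" always refers to the intervals, not the
samples. Two windows dominated by atmospheric water vapour and CO₂ —
1825–1915 nm and 2470–2500 nm, treated as closed intervals — are masked
by default (122 samples), leaving 2029 usable samples. Band lookups for
index formulas use the nearest unmasked sample within 3 nm of the
requested wavelength (the spectroradiometer's native VIS–NIR sampling
interval); equidistant ties resolve to the lower wavelength. A lookup
with no usable sample raises a missing-band condition that downstream
index evaluation converts into an explicit missing value with a reason,
never a silent zero.

## Spectral reflectance indices

The 20 indices live in a declarative registry (name, family, required
wavelengths, formula string), evaluated in a restricted environment and
exportable as JSON so users can add indices without code changes.
Missingness propagates per index: a masked required band, a division by
zero, or a non-positive radicand in SWSI-1/2 (whose denominators are
√(R₁₃₂₆ − R₁₅₀₇) and √(R₉₀₅ − R₉₇₂)) yields NaN plus a reason. Values
are not clipped; out-of-range results from invalid inputs surface
as-is. Two registry quirks are kept deliberately because the registry
is authoritative for this analysis: BNDVI uses 970 nm as its NIR term,
and WBI pairs 1500 nm with 531 nm. NMDI is implemented in the standard
normalized multi-band drought form
(R₈₆₀ − (R₁₆₄₀ − R₂₁₃₀))/(R₈₆₀ + (R₁₆₄₀ − R₂₁₃₀)).

## Stress tolerance indices

Per-genotype GYc and GYs are means over years × replicates before index
formation. The five indices are YSI = GYs/GYc,
SSI = (1 − GYs/GYc)/(1 − GȲs/GȲc), STI = GYc·GYs/GȲc² (Fernandez),
TOL = GYc − GYs, and GMP = √(GYc·GYs), with GȲc/GȲs the unweighted
means of the per-genotype means. SSI is undefined when the grand means
coincide (error), and a grand salinity mean above the control mean only
warns. Report tables round half-up to 2 decimals; internal values stay
unrounded.

## Genotype grouping

Clustering uses all seven features (GYc, GYs, YSI, SSI, STI, TOL, GMP),
z-standardized with the population standard deviation (idempotent;
constant features are an error), Euclidean distances, and Ward's
minimum-variance linkage, cut to k = 3 by default. Standardization and
the distance metric are this package's choices — the clustering
convention itself only fixes "Ward minimum variance" — and are recorded
here as such. Semantic labels are derived from group feature means:
highest GYc and STI → salt-tolerant (a disagreement between the two is
a tie error requesting manual labels); of the remaining two, higher YSI
and lower SSI → moderately salt-tolerant; the last → salt-sensitive.
The dendrogram serializes to Newick with branch lengths equal to
merge-height differences.

## Correlation screening

Correlations are Pearson r on genotype means within a scope (per year
or across years; genotype means are used because the screening
convention's n equals the number of genotypes). Significance uses the
exact two-tailed critical value r* = t*/√(t*² + n − 2); at n = 64,
α = 0.05 this is 0.246 → 0.25 at 2 d.p. Strength bins are sign-blind
and assigned upward at boundaries: ns below r*, weak < 0.50,
moderate < 0.70, strong ≥ 0.70. No multiple-testing correction is
applied by default, matching the screening convention; Holm adjustment
is available behind a flag. Constant columns give undefined (NaN)
cells flagged non-significant.

## Stepwise selection and group fits

SMLR is forward entry (smallest partial-F p-value, threshold 0.05) with
backward elimination (stay threshold 0.10), iterated to a fixed point;
`alpha_remove < alpha_enter` is rejected to prevent cycling. Candidate
order is the registry listing order, which makes tie-breaks between
duplicated candidates reproducible. Once the current model's R² is
within 1e-10 of 1, entry stops: partial p-values computed on round-off
residuals carry no information. With 10 independent null candidates at
n = 64 the first-entry family-wise rate is ≈ 1 − 0.95¹⁰ ≈ 0.40 — a
property of uncorrected stepwise entry worth knowing before trusting a
selected model. The final model is refit by OLS; R² = 1 − SSE/SST and
RMSE = √(SSE/n) (the n-denominator is configurable via `rmse_ddof`).
Per-group fits compare linear and quadratic forms and keep the
quadratic only when it raises R² by more than 0.01 (parsimony
tie-break); significance stars (*, **, ***) follow the overall-F
p-value at 0.05/0.01/0.001.

## Split-plot ANOVA

Per-year, fixed effects, balanced layouts only. Sums of squares follow
the classical means decomposition; the whole-plot error is the
Rep × ST interaction, and Error(b) is the residual. ST is tested
against Error(a); G and ST × G against Error(b). For r = 3, a = 2,
b = 64 the degrees of freedom are 2/1/2/63/63/252 (total 383). The
combined-years mixed model (years random) is out of scope; genotype
effects on STIs, which have one value per genotype and year, use a
one-way RCBD ANOVA with years as blocks.

## Synthetic trial generator

The generator is the package's stand-in for field data and is labelled
as such. It emulates: 64 genotypes in three planted groups of 25/19/20;
group mean control yields (6.23, 5.45, 5.18) t ha⁻¹ and mean stability
ratios (0.65, 0.63, 0.76); two years with deterministic offsets
±0.135 t ha⁻¹ (matching the observed between-year shift in treatment
means); three replicates with plot noise sd 0.20 t ha⁻¹. Per genotype,
GYc is truncated-normal around its group mean (sd 0.12) and YSI
truncated-normal (sd 0.02) within (0.40, 0.90), the stability range
observed across the panel rounded outward; GYs = YSI·GYc.

Latent canopy traits — chlorophyll c, biomass b, water status w in
(0, 1] — increase affinely with plot yield and are reduced
multiplicatively under salinity (water most, factor 0.82), with
Gaussian trait noise sd 0.03. Reflectance is a logistic red-edge step
(centre 715 nm, width 12 nm) from a visible shelf (0.12) to a NIR
plateau 0.28 + 0.22·b, declining linearly beyond 1300 nm with slope
proportional to 0.20 + 0.45·w, minus Gaussian absorption wells:
pigment wells at 450 and 680 nm (depth 0.02 + 0.10·c, widths 40/28 nm,
leaving the 550 nm green peak) and water wells at 970, 1170, 1450 and
1950 nm (depths 0.04 + 0.10·w, 0.03 + 0.08·w, 0.12 + 0.28·w,
0.16 + 0.34·w; widths 35/45/55/75 nm), which also produce the local
SWIR maxima near 1640 and 2200 nm. Smooth wavelength-correlated noise
(white knots every 80 nm, cubic interpolation, sd 0.004) is added and
the curve clipped to [0.01, 0.99]. By construction the salt-tolerant
group has the lowest visible and highest NIR reflectance and the
sensitive group the lowest NIR under salinity.

**What the generator does not emulate.** The within-group yield spreads
are deliberately tight so that the planted three-group structure is
recoverable by clustering (mean adjusted Rand index ≈ 0.94 over 20
seeds with the defaults); real panels show wider within-group variation
(observed full ranges of roughly 3.9–7.8 t ha⁻¹ under control), partly
from heavier tails and trait structure a three-component Gaussian
mixture cannot carry. Generated index values therefore sit in plausible
but not range-matched intervals, and passing recovery tests demonstrate
correctness of the machinery under separable conditions, not expected
performance on an arbitrary field panel. Radiative-transfer realism
(PROSPECT/SAIL-grade physics), soil background and view geometry are
out of scope.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` seeded
explicitly; the same seed gives bit-identical trials. Stochastic
self-checks use fixed problem sizes chosen as the package's own test
conditions: 20 seeds for cluster recovery, 100 seeds for stepwise
first-pick recovery (on one full-size trial's genotype-mean indices,
true R² ≈ 0.7), and 1000 null replicates for the type-I error of the
correlation flag. Exact comparisons pin the index evaluator to an
independent direct-arithmetic oracle at 1e-12 and OLS to the normal
equations at 1e-10.

## Known limitations

- Per-year fixed-effects ANOVA only; no REML/mixed combined-years
  analysis, no unbalanced designs.
- Stepwise selection inherits the usual selection-inference caveats
  (optimistic R², uncorrected entry tests).
- The semantic labelling of clusters assumes the three-group convention
  and errors on ambiguous profiles rather than guessing.
- Yields are consumed as already moisture-adjusted t ha⁻¹; no
  agronomic preprocessing is performed.
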