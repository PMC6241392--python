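# Methods

## Data model and ingestion

Events are plain `pandas.DataFrame`s: one row per event, one column per
channel, plus `sample_id` and the annotation columns `bead_group` and
`analyte_id` (object dtype; `None`/`NaN` = unassigned or noise). The
ingestion order is fixed: boundary-event removal on the two scatter
channels, then the arcsinh transform of the bead channels, then
closed-interval range filters. The format does not dictate this order;
removing saturated events before transforming keeps the boundary test a
simple equality on the raw detector scale, and filters are applied last
so scatter cut-offs are written in detector units while bead-channel
cut-offs are written on the transformed scale (the scale on which they
are chosen in practice).

Boundary events are those *equal* to a channel's boundary value, ties
included; the boundary defaults to the observed per-channel min/max and
is replaced by the `$PnR` detector range when the FCS metadata provides
one. In the degenerate case of an all-constant channel every event is
on the boundary; the operation then empties the table and emits a
warning rather than guessing.

The FCS reader/writer is minimal by design: list mode, `$DATATYPE`
F/D/I, `$PnN` names with `$PnS` fallback, `$PnE` log-amplification
decoding, FCS 3.0/3.1 with tolerant 2.0 handling. Escaped TEXT-segment
delimiters are not supported and raise a clear error. Files written by
the synthetic module are FCS 3.1, float32, little-endian.

Sample roles come from file names: `C<int>` marks a standard (C7 = top
of the series, C0 = blank), `S<int>` an experimental sample; both
patterns are configurable regexes with one capturing group and the full
multi-digit number is parsed, so panels with ten or more standard
levels name cleanly.

## Bead identification

Identification is positional: within a stage, clusters are ranked
ascending by their center along the first clustering channel (ties by
the second) and assigned the caller's ID list in order. The panel
therefore *is* the contract — analytes must be listed from low to high
classification intensity. For the two-dimensional scatter stage the
panel group listed first is assigned to the lowest-FSC cluster; the
mapping is overridable via `group_order` because which bead group is
physically the smaller one is a property of the kit, not of the
algorithm.

Engines:

- **PAM** (authored here): BUILD initialization plus best-improvement
  SWAP descent on the full dissimilarity matrix, restarted from eight
  seeded random medoid sets. The restarts cost little at the subset
  sizes PAM is used at and remove the rare local optima of a single
  steepest descent; the objective (total Euclidean dissimilarity to
  the nearest medoid) never increases within a descent.
- **CLARA** (authored here): PAM on `n_subsets = 5` random subsets of
  size `min(n, 40 + 2k)` (the classical defaults), each candidate
  medoid set scored against *all* points; with `subset_size >= n` it
  degenerates to exact PAM. This is the pipeline default — subsampling
  makes it fast on pooled event files and deterministic under a seed.
- **k-means / DBSCAN / Gaussian mixture**: scikit-learn, with k-means++
  and 10 restarts, and full covariances plus 3 EM starts respectively.
  DBSCAN infers the cluster count from density, so a count differing
  from the expected `k` raises an error instead of silently
  mislabelling positionally-assigned analytes.

**Trimming.** A fraction `trim` of each cluster's members is discarded:
members are ranked by Euclidean distance from the cluster's center
after standardizing each dimension by the cluster's own spread (the raw
numerical range of a channel depends on the detector, so unstandardized
distances would make the fraction scale-dependent), and the
`ceil(trim * m)` most distant are set to noise. The center is the
per-dimension mode of a 1-D Gaussian KDE (Silverman bandwidth,
512-point grid) — cheap and stable; a joint multivariate KDE mode would
be a defensible alternative and is a known divergence risk. Trimming is
a single pass: the center is estimated once, before removal, not
re-estimated iteratively.

By default all samples are pooled before clustering so that the
clustering decision is identical for every sample; `per_sample`
overrides this for drifting acquisitions.

## Quantification

MFI per (sample, analyte) is the geometric mean by default
(intensities live on a log scale); harmonic and arithmetic means are
available for special cases and both positive-only means fail loudly on
non-positive intensities, naming the sample and analyte.

The standard series assigns, over the numerically ordered unique
standard numbers, `C0 / D^i` from the top and 0 to the last sample (the
blank). Duplicate measurements of the same standard level share its
concentration; passing literally duplicated numbers to `calc_std_conc`
is an error, since the order of a series with ties is ambiguous.

The curve is fitted by trust-region nonlinear least squares
(`scipy.optimize.least_squares`) of log₁₀ MFI on log₁₀ concentration,
blanks excluded (log of zero); the blank is kept only as QC context.
Start values come from the data (`c`/`d` from the response range
extended by 5%, `e` from the dose nearest mid-response, slope sign from
the dose–response correlation) with a small multistart over slope
magnitudes; the asymmetry is bounded to `[1e-3, 1e3]`. The parameter
covariance is `sigma² (JᵀJ)⁻¹` from the Jacobian at the optimum. A flat
response raises instead of returning a degenerate curve.

Identifiability note: in the 5PL the inflection `e` trades off against
`b` and `f`, so individual parameters are estimated far less precisely
than the curve itself; the 4PL pins `e` down well. Concentration
estimates depend only on the fitted curve and are unaffected.

Inverse estimation applies the closed-form inverse of the 5PL and
reports `10^x̂`. The error is the delta-method standard error of `x̂`
with respect to the curve parameters only — response-measurement error
is *not* propagated — back-transformed to a multiplicative factor; this
is a deliberate, documented choice, not an assertion about what other
tools report. Responses at or beyond the asymptotes are reported
missing with an `out_of_range` flag rather than extrapolated; such
samples sit outside the curve's informative range and need re-dilution,
not arithmetic.

## Synthetic experiments

The generator emulates a 13-plex growth-factor experiment: 8 standard
levels (four-fold dilution from 50,000 pg/ml, blank last) and one
experimental sample, in duplicate — 18 files of 2,000 events each by
default, enough for ~150 beads per analyte, a realistic acquisition
depth. Scatter populations are bivariate Gaussians 8 sd apart (3 sd in
`hard` mode); classification means are spaced 0.8 apart (sd 0.08) on
the arcsinh scale, strictly increasing within each group. The reporter
response is generated from per-analyte 5PL curves on the
log₁₀(arcsinh PE) scale with asymptotes in [0.30, 0.40] and
[1.10, 1.18], slopes in [−3.6, −3.0], inflections in [2.7, 3.0] log₁₀
pg/ml and asymmetry in [0.8, 1.3]; the experimental concentrations lie
within ±0.45 decades of each inflection, i.e. inside the assay's
working range. Noise is lognormal: a per-(sample, analyte) shift of
sd 0.02 on log₁₀ MFI plus per-event spread of sd 0.05. 0.5% of events
are saturated at the scatter-detector limit. Raw channel values are the
`sinh` of the transformed values, so files round-trip through the real
ingestion path.

What the generator does **not** emulate: spectral spillover and
compensation, detector drift within a run, doublets/aggregates,
heavy-tailed autofluorescence, and bead-count imbalance between
analytes. Passing tests therefore demonstrate the correctness of the
pipeline's logic and its statistical behavior under the stated noise
model, not robustness to every artifact of real cytometry data.

Problem sizes used by the test suite (800–2,000 events per sample,
20-seed end-to-end replications) were chosen as the smallest sizes at
which the statistical assertions are stable.

## Known limitations

- The packaged panel's analyte-name/ID mapping is a plausible
  reconstruction of the commercial 13-plex and all start concentrations
  default to 50,000 pg/ml; both are overridable via an external panel
  file.
- No limit-of-detection/quantification statistics, plate-layout
  normalization, replicate averaging (both duplicates are reported), or
  de-noising beyond trimming.
- DBSCAN parameterization (`eps`, `min_pts`) is left entirely to the
  user; no automatic method selection is attempted.
- The concentration error factor understates total uncertainty because
  it omits the MFI measurement error of the unknown sample.
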