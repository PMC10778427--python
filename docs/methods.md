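# Methods

This note documents the models implemented in `tumoxmap`, the synthetic
phantom that stands in for patient data, the numerical choices made
where the design was open, and what the passing tests do and do not
demonstrate.

## The sqBOLD signal model and its estimators

The FLAIR-ASE log-signal is piecewise in the spin-echo shift τ: a
quadratic regime −0.3·(R₂′τ)²/DBV below the transition τc and a linear
regime DBV − R₂′τ above it, both on top of the baseline
ln S₀ − R₂·TE. τc is fixed at 16 ms, which is deliberately also a
sampled shift; the transition sample is assigned to the linear branch
throughout (simulator and both estimators agree on this convention, so
recovery is exact on model data). From a single-TE acquisition only the
combination ln S₀ − R₂·TE is identifiable; it is stored as one nuisance
volume (`baseline_ln`) rather than pretending to separate proton
density from R₂.

Two estimators are provided with the same estimand:

* **log-linear** (default): OLS of ln S against τ over the samples with
  τ ≥ τc gives −R₂′ (slope) and the intercept c; the τ = 0 sample gives
  the baseline directly, so DBV = c − ln S(0). Closed-form,
  deterministic, and exact to machine precision on noiseless model data
  because every fitted point then lies on the linear branch.
* **nonlinear least squares**: bounded (R₂′ ∈ [0, 100] s⁻¹,
  DBV ∈ (0, 0.5]) fit of the full piecewise model over both regimes,
  initialised from the log-linear solution. It cannot degrade the
  noiseless solution (the initialisation is already a zero-residual
  fixed point) and under noise it weights the quadratic-regime samples
  the closed form ignores.

The reference clinical analysis uses variational-Bayes fitting whose
free-energy convergence criterion is not reproducible from published
descriptions; deterministic estimators with an explicit failure
classifier were chosen instead so that every number in this package can
be recomputed bit-for-bit.

OEF follows as 3·R₂′/(4π·γ·B₀·Δχ₀·Hct·DBV) with γ = 267.5×10⁶
rad T⁻¹ s⁻¹, B₀ = 3 T, Δχ₀ = 0.264 ppm (converted as 0.264×10⁻⁶; the 4π
cgs→SI factor is explicit in the formula) and Hct = 0.4. OEF is stored
as a fraction and *not* clamped: values above 1 occur in practice
(macroscopic B₀ effects) and are left to the error-mask logic and to
the reader. Sub-machine-noise parameter estimates (|x| < 10⁻¹²), which
arise when fitting an exactly constant signal, are snapped to zero so
that flat voxels report OEF = 0 rather than 0/0.

### Failure classification

A voxel enters the binary error mask when any of the following holds:
non-finite fit, R₂′ < 0, DBV < 0 or DBV > 0.5, DBV = 0 with R₂′ > 0,
normalized RMS residual above a threshold, sub-floor signal intensity
(default floor: 5 % of the robust maximum of the τ = 0 volume), or a
signal peak at a shift *beyond* τc. Flagged voxels are zeroed in all
parameter maps, matching the display convention of zeroing failure
voxels, and are excluded from every downstream average.

The peak criterion deserves a note. The naive rule "flag when the
signal maximum is not at τ = 0" is wrong under this signal model:
whenever DBV > R₂′·τc — true for the default edema and nonenhancing
parameters — the linear branch at τc sits *above* the τ = 0 baseline,
so a clean, model-consistent voxel has its ln-signal maximum at the
first linear sample. Since the linear branch strictly decreases, the
model can place the maximum only at τ = 0 or τ = τc; a maximum strictly
beyond τc (such as the 28 ms peak used in the corruption mode) cannot
arise from the model at all and is what the classifier flags.

The residual gate defaults to RMS residual > 0.05 of the voxel's
ln-signal range. This is calibrated for validation work near the
noiseless regime; at realistic noise (σ of 1–2 % of S₀ the ln-signal
noise is a large fraction of the decay range) it flags genuine fits and
should be relaxed in proportion to the expected noise, or disabled
(`residual_frac=None`). The pipeline config exposes it.

## DSC perfusion and vessel size

Signal-time curves are converted as ΔR₂ = −ln(S/S̄)/TE after discarding
the first four pre-steady-state volumes; the published processing
delegates this conversion to prior work, and the universal DSC form is
required anyway by the units of the vessel-size formula. The baseline
S̄ is the mean over the volumes between the discard point and two
samples before the bolus entrance (found by a two-pass detection: mean
curve threshold baseline + 3 SD sustained for 2 samples).

CBV is the trapezoidal integral of leakage-corrected ΔR₂*(t) from bolus
entrance to exit, divided by the mean over the contralateral-WM mask
(so contra-WM averages exactly 1, and the map is invariant to global
intensity scaling). The BSW leakage correction fits each voxel curve to
K₁·R(t) − K₂·∫R dt′, R being the mean curve over a non-leaky reference;
when no reference mask is supplied, a first pass over all brain voxels
estimates K₂ and the reference is rebuilt from |K₂| ≈ 0 voxels. The
correction is invariant to the scale of R, so the exact membership of
the reference set is uncritical as long as it is non-leaky.

Vessel size is 0.867·(CBV·ADC)^½·ΔR₂*peak/ΔR₂peak^1.5 with peaks taken
inside the bolus window from the corrected gradient-echo curve and the
*raw* spin-echo curve (whether the spin-echo channel should also be
leakage-corrected is unsettled; the SE leakage term is much smaller and
is omitted). With ADC in mm²/s and rates in s⁻¹ the bare formula yields
mm; maps are reported ×1000 in µm, the conventional display unit.
Vessel size is evaluated only where normalized CBV exceeds 0.05,
guarding the 0/0 amplification in avascular voxels. ADC comes from a
log-linear fit over b ∈ {0, 10, 1000} s/mm².

## The phantom

Geometry is a brain ellipsoid split into hemispheres: contralateral
white-matter core with a gray-matter shell and a small CSF blob, and a
tumor built from nested ellipsoids (necrosis inside enhancing inside
edema) plus a disjoint nonenhancing blob. Region geometry is
synthetic by design — only the label semantics matter for the mask
logic under test.

Default region parameters follow group-level tissue values (e.g.
contra-GM R₂′ = 5.13 s⁻¹, DBV = 4.3 %, CBV = 1.66, vessel size
16.24 µm; elevated R₂′ ≈ 7.9 s⁻¹ in enhancing tumor; CSF given high ADC
of 3×10⁻³ mm²/s), with contra-WM as the CBV reference at 1.0 and a
leakage coefficient K₂ = 0.02 injected only in the enhancing region.
Noise is Gaussian on magnitude by default (appropriate at SNR ≳ 3) with
Rician available by flag; σ is specified as a fraction of S₀.

The DSC simulator emits a unit-peak gamma-variate bolus (onset 20 s,
α = 3, β = 1.5 s — no arterial input function is prescribed anywhere,
so a fixed canonical shape is used) scaled per voxel so that the bolus
integral normalized to contra-WM equals the true CBV exactly. The
spin-echo response is scaled so that the Kiselev identity holds on the
*sampled* curves (using the attained discrete peak rather than the
continuous one); without this the round trip would carry a spurious
~1 % error purely from where the TR grid happens to sample the peak.
Leakage enters as −K₂·∫R dt′ on the measured gradient-echo rate — the
same model family the BSW estimator inverts, which is what makes the
noiseless round trip exact rather than merely close.

A "shifted-peak" corruption mode re-centres the quadratic branch at a
chosen shift (default 28 ms), reproducing the anomalous
peak-away-from-zero behaviour seen in some metastases, to exercise the
error-mask logic. The functional form of this corruption is invented;
only its observable signature (argmax beyond τc) matters.

Histology tables are coupled to the ground truth through strictly
monotone links (diameter affine in true vessel size, density affine in
true CBV, H-score sigmoidal in true OEF) plus Gaussian scatter; with
zero noise the induced Spearman correlations are exactly 1, and with
`strength=0` the links are null — the two calibration points the
statistics tests need.

What the phantom does **not** emulate: anatomically realistic
geometry, partial-volume mixing at region borders, motion,
macroscopic B₀ gradients, diffusion narrowing of the ASE signal, or
spatially correlated noise. Passing recovery tests therefore
demonstrate correctness of the estimators under their stated model, not
robustness to every physical confound of patient data.

## VOI analysis, targeting, statistics

Per-VOI summaries are medians and a single-width IQR (Q3 − Q1, linear
interpolation), computed after removing error-mask voxels;
group-level values are means ± SD of per-subject medians. VOI-averaged
decay curves are aligned by an additive offset so every curve starts at
the contra-GM τ = 0 value; the offset shifts means only, SDs are left
untouched. Contralateral GM/WM masks come from probability maps
thresholded strictly above 0.9.

Biopsy clusters are 26-connected components of voxels strictly above
the 80th (or below the 20th) percentile of the unflagged tumor voxels
(nonenhancing ∪ enhancing ∪ necrosis — edema is excluded from both the
percentile population and the targets, since biopsies there are
prohibited). "At least nine voxels arranged cubically" cannot be a
literal cube; it is read as ≥ 9 voxels containing a full 2×2×2 block,
with the in-plane alternative selectable via `require_block=False`.
Overlapping clusters across metrics merge into one target ranked by
(number of supporting metrics, overlap size, extremity, metric order
OEF → CBV → vessel size); the neurosurgeon's choice among candidates is
replaced by deterministic rank truncation. Target values are means over
the 3×3×3 neighborhood (27 voxels; the literal 10-voxel reading is
available as `mode="ten"`), clipped at volume borders and excluding
flagged voxels.

Statistics wrap SciPy's tie-corrected Kruskal–Wallis, Mann–Whitney
(exact enumeration when both n ≤ 8 and no cross-group ties) and
Spearman tests; the all-tied Kruskal–Wallis case is defined as H = 0,
p = 1. **No multiple-testing correction is applied** — pairwise
p-values are reported raw and annotated, mirroring the comparison
design this package reproduces. Rows with missing values are dropped
listwise per tested pair and counted in the output.

## Problem sizes and tolerances

Recovery tests run on 32³ phantoms (20³/16³ for the repeated-run
studies), 90-volume DSC series at TR = 1.5 s, and the 13-shift ASE
scheme; these sizes keep the full suite and the acceptance script in
the tens of seconds while leaving hundreds-to-thousands of voxels per
region. Noiseless round-trip tolerances are 10⁻⁹ (relative, sqBOLD),
10⁻³ (absolute, normalized CBV) and 1 % (relative, vessel size);
statistical calibration accepts false-positive rates in [0.03, 0.07]
at α = 0.05 over 500 simulations. Determinism is by construction:
every random draw flows from a single integer seed through
`numpy.random.default_rng`.

## Known limitations

* The log-linear estimator ignores the quadratic-regime samples; under
  heavy noise its DBV estimate inherits the τ = 0 sample's noise
  directly.
* The error-mask residual gate needs manual re-calibration away from
  the near-noiseless regime (see above).
* OEF group statistics depend on whether one averages voxels or
  per-subject medians; this package reports medians per subject, then
  means across subjects.
* The BSW inversion is exact only against its own leakage model; real
  extravasation kinetics (T₁ shortening, bidirectional exchange) are
  richer.
* Registration between modalities is assumed done: all inputs must
  share one grid (strict shape equality, no resampling).
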