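# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the design decisions that were genuinely open.

## Geometry

**Coordinates and numbering.**  Ensembles are ordered frames of labelled
atomic coordinates in Å.  Residue numbering is the author (PDB) numbering,
1-based; residue ranges such as 3–31 are inclusive in that numbering.
Multi-model PDB is the interchange format (one frame per MODEL); binary
trajectories (DCD/XTC + PDB topology) are read through mdtraj when the
optional extra is installed.  Alternate locations keep altloc ' ' or 'A';
insertion codes are rejected with an explicit error (none of the benchmark
systems use them).

**Superposition.**  Least-squares rigid-body fits use the Kabsch SVD
algorithm with the determinant correction that excludes reflections.
Selections with fewer than three atoms, or collinear selections (rotation
about the line undetermined), raise a degenerate-geometry error.  The unit
tests and the acceptance script cross-check the result against an
independently implemented quaternion (Horn) eigenvalue method on 1,000
random instances; agreement is at machine precision.

**Dihedrals.**  φ(i) is C(i−1)–N(i)–CA(i)–C(i) and ψ(i) is
N(i)–CA(i)–C(i)–N(i+1), IUPAC sign convention (trans = 180°, cis = 0°),
degrees in (−180°, 180°] externally, radians internally.  Terminal residues
lacking a defining atom raise an explicit error rather than returning NaN.

**Amide protons.**  Experimental structures often lack hydrogens.  The
backbone H of residue i can be reconstructed along the external bisector of
C(i−1)–N(i)–CA(i) at 1.01 Å (ideal amide geometry, in-plane, trans to both
heavy-atom bonds); reconstructed atoms are flagged in ensemble metadata.

## NMR observables

**Scalar couplings.**  J(φ) = A cos²(φ+δ) + B cos(φ+δ) + C is evaluated per
frame and averaged.  Because the parameters are fixed, averaging J per frame
is identical to averaging cos²/cos terms first; we average J for clarity.
The coefficient sets for the four backbone couplings (HNHA δ=−60°, HNCO
δ=180°, HNCB δ=+60°, HACO δ=+120°) are configuration data with defaults
transcribed from commonly used literature parameterisations; every report
records the set in effect, and custom sets can be supplied in the config.
Agreement with experiment is the RMS difference over matched
(residue, type) rows; unmatched rows are listed in the result, never
silently dropped, and are not imputed.

**RDCs and the Q factor.**  For each residue the normalised bond dyadic
⟨b bᵀ⟩ is averaged over frames after superposing every frame on the first
(default selection: all backbone heavy atoms), so a single alignment tensor
describes the whole ensemble per medium and the fit stays linear.  The five
independent components of the traceless symmetric Saupe tensor are solved by
least squares from D = tr(S⟨b bᵀ⟩); the pair-specific maximal coupling is
absorbed into the tensor (scale = 1 Hz).  Fewer than five couplings or a
rank-deficient design (degenerate bond directions) raise an
under-determined error.  Q = sqrt(Σ(Dc−De)² / ΣDe²) without any theoretical
Da normalisation — the simplest variant of the standard definition.  Note
that when the same noisy data are used for fitting and scoring, the fit
absorbs five degrees of freedom, so for N couplings with noise σ the
expected Q is σ·sqrt(1−5/N)/rms(D), slightly below σ/rms(D); the acceptance
checks use the corrected expectation.

**Order parameters.**  The internal ACF
C(t) = ⟨P₂(μ(τ)·μ(τ+t))⟩, P₂(x) = (3x²−1)/2, is estimated over all
overlapping time origins (dividing by the number of terms at each lag)
after tumbling removal by superposition.  S² is the mean of C(t) over the
lag window τc·(1±0.2); the ±20% half-width is a package default since no
canonical window exists, and it is configurable.  τc is user input (the
experimentally determined rotational correlation time), never estimated
from the trajectory.  Estimates outside [0, 1] beyond numerical tolerance
are clipped with a warning.  The superposition selection for tumbling
removal defaults to all backbone heavy atoms and is exposed in the API for
cases where only secondary-structure residues should define the fit.

**Error bars.**  Standard errors come from contiguous block averaging: the
trajectory is split into 5 equal blocks by default, the metric recomputed
per block (including the tensor refit for Q), and the SEM taken across
blocks.  Constant per-block estimates give SEM = 0 exactly.

## Conformational states

**Helicity.**  A residue is helical in a frame iff (φ, ψ) falls in the box
φ ∈ [−100°, −30°], ψ ∈ [−67°, −7°] *and* it belongs to a run of ≥ 3
consecutive in-box residues.  The box-plus-run rule is a documented stand-in
for the several non-identical helicity definitions in circulation; box and
run length are configurable and recorded in reports.  Terminal residues
with undefined φ or ψ are never helical and are excluded from fraction
denominators.  The helical fraction is the mean indicator over frames and
assignable residues.

**Dual-cutoff detection.**  Given per-segment Cα-RMSD series and per-segment
(fold, unfold) thresholds with fold < unfold, a frame triggers *fold* when
all segments are simultaneously below their fold thresholds and *unfold*
when all are simultaneously above their unfold thresholds; otherwise the
previous state persists (hysteresis suppresses recrossing noise).  The
simultaneity rule is applied uniformly to both trigger directions and to
all systems.  Frames before the first trigger are "undetermined"; the first
crossing establishes the state without counting as an event, so events
record only folded↔unfolded transitions, alternate strictly, and their
counts differ by at most one.  Folded fractions are taken over determined
frames only.  Event frame indices are 0-based.  Presets:

| preset | segments (fold Å / unfold Å) |
|---|---|
| villin-2F4K | 3–31 (1.2/5.0), 3–18 (0.9/4.6), 14–31 (0.9/2.5) |
| ww-2F21 | 2–33 (2.0/7.0), 8–22 (1.1/5.8), 12–18 (0.6/1.8), 19–30 (0.9/3.8) |
| cln025 | 1–10 (1.0/4.0) |

**Melting curves.**  One fraction per temperature with block-averaged SEM,
sorted by ascending temperature; duplicate temperatures are an error.
Temperature is a label attached to each per-temperature frame set — no
reweighting across temperatures is performed (inputs are assumed to be
per-rung ensembles from a tempering protocol or independent runs).

## Scoring

Each force field gets an integer 0–2 per test family (0 = reasonable
agreement, 2 = severe discrepancy) and the total is their sum (0–6).  The
packaged reference table stores expert-assigned scores, which are explicitly
subjective; the years follow the convention of dating a force field by its
most recently published correction.  Ranking is competition style
("1224", ties share the minimum rank) and the trend statistic is the
Spearman rank correlation between year and total (all-equal totals return
0 with a warning).  `apply_rubric` offers a reproducible alternative that
maps continuous metrics through strictly ordered cut-points (boundary values
fall in the lower class); its cut-points are package-defined, flagged as
such in every report, and never silently substituted for the reference
scores.

## Synthetic generators

All generators take an explicit seed and are byte-reproducible.  They
emulate the *statistical structure* the analysis assumes — they are not
physics simulators (no energetics, no solvent, no kinetic realism beyond
what is stated), so passing tests validate the analysis machinery, not any
force field.

**Two-state traces.**  A continuous-time Markov chain with exponential
dwell times, discretised at the frame interval; per-segment RMSD emitted as
state level plus Gaussian noise (defaults 0.5 Å folded / 6.0 Å unfolded,
σ = 0.1 Å, versus 1.0/4.0 Å cutoffs).  The default design point is equal
rates 1/T with horizon 10 T starting unfolded — the regime in which a
perfectly balanced model yields about five folding and five unfolding
events.  Ground-truth events are the transitions of the frame-discretised
state sequence: dwells shorter than one frame are invisible at the emitted
resolution (≈1% of dwells at the default 0.01 T frame interval), so a
perfect detector can and does match the truth exactly.  A
coordinate-emitting variant jitters the reference structure (folded) or an
expanded decoy (unfolded) for end-to-end pipeline tests.

**Helix–coil.**  A Zimm–Bragg-type nucleation–propagation chain: coil
weight 1, helix weight w per residue with an extra factor σ for the first
residue of each helical run.  Exact marginals and means come from the 2×2
transfer matrix; samples are drawn by backward-weight conditional sampling
and are therefore exact draws, not MCMC.  Temperature dependence is van't
Hoff: w(T) = exp(−ΔH/R·(1/T − 1/Tm)) with defaults ΔH = −1.3 kcal/mol per
residue, Tm = 305 K, σ = 0.003, n = 15 residues, 10⁴ frames at
275–320 K — realistic alanine-rich-peptide territory that melts from ≈40%
to ≈6% helicity over the ladder.  The transfer-matrix mean is verified
against brute-force 2ⁿ enumeration for n ≤ 12.

**Cone ensembles.**  Per-residue N–H directions are redrawn every frame
uniformly within a cone of half-angle θ₀ about the reference orientation;
heavy atoms stay fixed, and an optional random global rotation+translation
per frame exercises the tumbling-removal step.  Because frames are
orientationally independent, C(t > 0) is flat at the analytic
S² = [cos θ₀ (1 + cos θ₀)/2]², which is attached as metadata.  This isolates
the ACF/plateau estimator; it does not emulate timescale separation between
internal motion and tumbling.

**RDC / coupling datasets.**  D = bᵀSb (+ Gaussian noise) from a known
random traceless symmetric tensor; J tables from per-residue φ distributions
through a given Karplus set.  Generating tensors and noiseless values are
recorded alongside the tables.

## Problem sizes and numerics

The test suite and the acceptance script use 10⁴-frame ensembles for
order-parameter and helicity recovery (sampling error ≲ 0.01 in S², ≲ 3 SEM
in helicity), 1,000 replicates for the two-state event expectation, 100
seeds for detector exactness and noisy-Q calibration, and 1,000 random
instances for the superposition cross-check — sizes at which the
statistical tolerances above are comfortably resolved on a single CPU in
seconds.  Least-squares solves use `numpy.linalg.lstsq` with rank checks;
tensor tracelessness is enforced to 10⁻⁹ relative; ACF lag 0 is pinned to
1 exactly.

## Known limitations

- The generators do not reproduce real conformational dynamics: no
  correlation between successive cone frames, no realistic RMSD
  distributions within a state, no cooperativity beyond the single σ
  nucleation factor.  Agreement on synthetic data demonstrates estimator
  correctness, not force-field quality.
- Chemical shifts, relaxation rates (R1/R2/NOE) and side-chain couplings
  are out of scope, as are temperature reweighting (WHAM/MBAR), kinetic
  models and free-energy surfaces.
- The Q factor implements the rms(Dexp)-normalised variant only; a
  Da-scaled variant would change absolute Q values but not rankings.
- Reading ensembles assumes whole molecules (no periodic-boundary imaging)
  and single-chain models.
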