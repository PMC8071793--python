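# Methods

## Force model

The kernel computes only short-range nonbonded protein–lipid pair
forces, in kJ/mol, nm and elementary charges, under the orthorhombic
minimum-image convention (triclinic boxes are rejected).

* **Coulomb**: plain truncation at `r_cut` = 1.2 nm with the electric
  conversion factor 138.935458 kJ mol⁻¹ nm e⁻². The reciprocal-space
  (mesh Ewald) part of electrostatics is out of scope; as a
  consequence the Coulomb force is discontinuous at the cutoff for
  charged pairs. This is an accepted approximation: the punctual-stress
  signal is dominated by contacts well inside the cutoff.
* **Lennard-Jones**: CHARMM-convention *force switch* between
  `r_switch` = 1.0 nm and `r_cut` = 1.2 nm. For each power-law term
  V = c/rᵖ (p = 12, 6) the radial force a/rᵖ⁺¹ (a = p·c) is augmented on
  the switch window by A(r−r₁)² + B(r−r₁)³ with

      A = −a[(p+4)r_c − (p+1)r₁] / [r_c^{p+2}(r_c−r₁)²]
      B = +a[(p+3)r_c − (p+1)r₁] / [r_c^{p+2}(r_c−r₁)³]

  so force and its derivative vanish at `r_cut` and join the plain
  force C¹-continuously at `r_switch`. Whether the original
  force-distribution analysis used the potential-switch or force-switch
  variant is not documented; the force-switch choice is recorded here
  as an assumption.
* **Combination rule**: Lorentz–Berthelot (arithmetic σ, geometric ε),
  applied per atom pair from per-atom parameters.
* Only protein–lipid pairs are ever evaluated; intra-protein and
  intra-lipid forces do not exist in this model. Punctual stress is the
  per-residue scalar sum over lipid molecules of the magnitude of the
  per-lipid vector sum — the order (vector sum within a lipid, then
  magnitude, then scalar sum across lipids) matters and is fixed by the
  definition.

Frames are assumed extracted at a 40 ps stride (`stride_ps` default);
the stride only sets the time axis of the series.

## Difference-vector observable

Both reference structures share one atom ordering; the projection and
the fit use the same backbone selection. Frames are superposed onto the
*down* reference by the Kabsch procedure (proper rotations only,
implemented via `scipy.spatial.transform.Rotation.align_vectors`);
collinear or too-small selections raise a degenerate-geometry error.
The observable is the unnormalised projection (nm²); a state label is
1 iff x exceeds a configurable threshold whose default 0 is the natural
separatrix, since x(r_avg) = 0 and x(r_up) = −x(r_down) =
½·Σ|r_up−r_down|². Normalising by Σ|r_up−r_down|² is available for
plotting but never used in the analysis.

## PLS-FMA

Single-response NIPALS PLS1 on mean-centred features and observable.
Features are *not* variance-scaled, so coefficients remain comparable
across residues in physical force units. Per component: weight w ∝
X_resᵀy_res (unit norm), scores t = X_res w, X- and y-deflation by the
rank-one score contribution. The K components compose into a single
coefficient vector b = W(PᵀW)⁻¹q with predictions ŷ = ȳ + (X−x̄)b; at
K = rank(X) this reproduces ordinary least squares. Requesting more
components than the data's rank truncates the model with a warning;
a zero-variance observable is an error.

The default component count is chosen by held-out-replica correlation:
the smallest K whose mean held-out Pearson r improves by less than 0.01
over K−1, capped at 20. On the calibrated synthetic ensemble this
selects K = 2.

The "contribution" of component k is defined as R² of the k-truncated
model divided by R² of the full model on the same data (the printed
definition of the quantity is not documented anywhere; this R² ratio is
the package's assumption and entry 1 is reported as the first-
eigenvector contribution). Per-fold coefficient vectors are aggregated
by sign-aligning against the first vector (PLS orientation is fixed by
the fit, but folds are aligned defensively) and averaging; the pairwise
cosine matrix is kept as a stability diagnostic.

## Cross-validation and metrics

Complete leave-one-trajectory-out: each replica is held out once, the
model is fitted on the remaining replicas only (the held-out frames
influence neither the means nor the weights — asserted bit-wise in the
tests). Transitioning replicas are scored by per-frame ROC AUC
(Mann–Whitney pair counting via average ranks, ties ½) using the
predicted observable as score against the per-frame state labels, and
by Pearson r between predicted and observed x. Control replicas, having
a single class, are scored by the per-frame false-positive fraction
(fraction of frames predicted past the threshold), matching the
convention of reporting percentages of frames rather than whole-
trajectory calls. Labels are per-frame; whether the original analysis
thresholded per frame or per trajectory is not documented, so the
per-frame choice is configurable.

Chain symmetry takes an explicit A→B residue pairing (no automatic
alignment), reports paired coefficients, their Pearson correlation, and
the partner-chain rank of each chain's top-k positive/negative
residues. Hotspot ranking breaks ties by ascending residue position for
determinism.

## Synthetic data

The generator defines the study conditions; its defaults are not tuning
knobs.

* **Ensemble shape**: 10 replicas — 7 "tension" replicas with a
  transition + 3 controls — of 500 frames × 521 features, matching the
  replica structure and feature dimension of the real study.
* **Latent transition**: controls sit at s ≡ −1 (down); transition
  replicas follow a logistic ramp from −1 to +1 with time constant
  ramp_width/4 (width 20 frames — sharp on the replica scale but
  smooth, as transitions spanning tens of ns appear at a 40 ps frame
  stride). The midpoint is drawn uniformly from frames 100–400,
  emulating transitions at roughly 50–300 ns within the analysed
  window. State labels are the indicator s > 0, hence monotone within
  transition replicas.
* **Features**: baseline + c·s(t) + N(0, σ) noise per frame and
  feature. Baselines are drawn once per ensemble from N(10, 2) to mimic
  nonzero resting stress; mean-centring in the PLS must absorb them.
  The planted coefficient vector c has 20 hotspot entries of magnitude
  1.0 with alternating signs (positive: stress grows through the
  down→up transition; negative: it drops). Feature noise σ = 2.0 is a
  calibration choice — the per-frame noise level of real force signals
  is not documented — exposed in the spec and chosen so the validation
  metrics land in a demanding but passing regime (AUC ≈ 0.99,
  r ≈ 0.84–0.91) rather than saturating trivially.
* **Observable**: s(t) scaled by 1.0 plus N(0, 0.1) noise — a clean
  but not noiseless reaction coordinate.
* **Toy systems**: protein residues stacked at 0.5 nm along z (the
  membrane normal), first half chain A, second half chain B; lipids
  alternate between placements strictly inside the switch radius
  (centre 0.4–0.8 nm from a protein atom) and strictly outside the
  cutoff (1.40–1.70 nm radially, which stays > 1.2 nm from every
  protein atom under the ±0.05 nm atom jitter). The placement plan is
  stored in metadata and verified by brute-force distance scans.
  Charges ∈ [−0.5, 0.5] e, σ ∈ [0.25, 0.35] nm, ε ∈ [0.2, 0.8] kJ/mol.
* **Toy trajectories**: the up reference is the down reference plus a
  random displacement field on protein atoms, orthogonalised against
  the six rigid-body modes and rescaled to the requested RMS. Because
  the field carries no net translation or rotation, the Kabsch fit of
  any noiseless interpolated frame onto the down reference is exactly
  the identity, making the midpoint and affine-interpolation identities
  hold to machine precision. Each frame is also returned under a random
  rigid motion to exercise the superposition step.

What the synthetic data does *not* emulate: correlated noise across
residues and time, lipid exchange dynamics, partial or reversed
transitions, and asymmetry between chains. Passing tests therefore
demonstrate correctness of the inference machinery and its behaviour
under the planted-signal regime, not performance on real membrane
trajectories.

## Problem sizes and determinism

All analyses are desk-scale by design: toy force systems stay under
~100 atoms (the brute-force oracle is quadruple-loop Python), and the
calibrated ensemble is 5 000 frames × 521 features, for which a full
leave-one-out validation takes a few seconds. Every generator and the
pipeline are pure functions of their configuration including the seed;
pipeline outputs land in a directory keyed by a hash of the
configuration, so reruns are bit-identical and never mutate inputs.

## Known limitations

* No reciprocal-space electrostatics, bonded forces, virial, or binary
  trajectory formats (multi-model PDB only; an adapter can feed
  coordinates from any reader as plain arrays).
* The Coulomb truncation discontinuity at 1.2 nm (see above).
* PLS coefficient equivariance under per-column rescaling holds exactly
  only in the K = rank limit; truncated PLS is scale-sensitive by
  construction, which is why features are kept in common physical
  units.
* Control-replica false positives depend directly on the state
  threshold; the default 0 is principled but arbitrary in the presence
  of observable noise.
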