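# Methods

## Model and scope

`refecho` computes the decay of two-pulse (Hahn) and refocused Hahn echoes
of a single electron spin (S = 1/2) coupled to a bath of protons, the
mechanism usually called nuclear spin diffusion. The model is fully
coherent: density-matrix propagation in Hilbert space with ideal,
instantaneous, electron-only pulses, no relaxation terms, and a
high-temperature initial state (electron polarization ⊗ maximally mixed
nuclei). Everything the echo does — including its decay — therefore
follows from the closed-system Hamiltonian

    H = ω_S S_z − ω_I Σ_n I_z^n + S_z Σ_n (A_zz^n I_z^n + A_zx^n I_x^n + A_zy^n I_y^n)
        + Σ_{m<n} b_mn (I_+^m I_−^n + I_−^m I_+^n − 4 I_z^m I_z^n),

whose nuclear part is block-diagonal in m_S (only S_z electron operators
appear), giving the two manifold Hamiltonians H_α/H_β used throughout.
Hyperfine couplings are point-dipole, computed from electron and proton
positions with the isotropic (Fermi-contact) part set to zero; b_mn is the
secular nuclear dipolar coupling, so the pair operator string above is
exactly the secular + flip-flop dipolar Hamiltonian. All couplings are
carried internally as angular frequencies (rad/s); files and reports use
Hz/kHz/MHz and microseconds.

Out of scope by design: finite/shaped pulses, T1 and other phenomenological
relaxation, instantaneous and spectral diffusion from electron–electron
couplings, deuteron (spin-1) dynamics (partial deuteration is modelled as
proton removal; deuteron flip-flops are ~40× weaker), quadrupolar nuclei,
and DFT-derived hyperfine tensors.

## Echo amplitudes

For a cluster with manifold Hamiltonians (H_α, H_β) the echoes are
evaluated from the eigendecompositions H_x = V_x Λ_x V_x†, so every point
of a delay grid is exact (no time-stepping error):

* Hahn: V(τ) = d⁻¹ Re Tr[U_β U_α U_β† U_α†], all propagators at time τ;
* refocused: V(τ1,τ2) = d⁻¹ Re Tr[W_A W_B†],
  W_A = U_α(τ2) U_β(τ1+τ2) U_α(τ1), W_B = U_β(τ2) U_α(τ1+τ2) U_β(τ1).

Both formulas reduce to phase sums over the overlap matrix S = V_α†V_β
(`_kernels.py`), which separates the refocused trace into τ1- and
τ2-dependent factors contracted by one batched matrix product — the step
that makes 10⁴–10⁵ cluster evaluations on a 2D grid affordable. Detection
is the real part of the normalized coherence-pathway overlap (matching
phase-cycled acquisition); a brute-force oracle (`exact_oracle`) propagates
the full 2^(N+1) density matrix through explicit π/2 and π rotations and
reads out Tr[ρS₊], and agrees with the trace formulas to ~1e-13.

A subtlety the oracle confirmed: the refocused echo is symmetric under
τ1 ↔ τ2 *exactly* only when the cluster Hamiltonian is real, i.e. when the
pseudo-secular components of all nuclei are coplanar (in particular when
they are omitted, as in the model Hamiltonian above written without them).
With the full lab-frame S_zI_x and S_zI_y terms, the relative azimuthal
phases of different nuclei make H complex and break the symmetry at the
~1e-7 level — an ESEEM-phase effect far below experimental visibility, but
relevant when asserting the symmetry numerically. The tests assert 1e-10
for the real model Hamiltonian and 1e-5 for the full one.

## Cluster correlation expansion

The bath signal is factorized as V = Π_C Ṽ_C with
Ṽ_C = V_C / Π_{C′⊂C} Ṽ_C′ over clusters C up to size k. Untruncated this
is an identity (verified against the oracle at 1e-8 on 3–5-proton baths);
truncation at k = 2–4 with a pair-coupling threshold makes ~500-proton
baths tractable.

Threshold semantics: a cluster is retained iff it is connected through
edges whose pair-coupling measure is at least the threshold (default
1.58 kHz). The default measure is the orientation-independent dipolar
coupling constant (µ0/4π)γ_H²ħ/(2πr³), i.e. a distance criterion
(1.58 kHz ↔ r ≤ 4.24 Å). This choice keeps the cluster set identical at
every powder orientation and reproduces the two- and three-cluster counts
expected for a ~500-proton bath at water density with this truncation; an
alternative measure using the orientation-dependent |b_mn| is available
(`edge="secular_b"`), as is a stricter all-internal-pairs rule
(`mode="all_pairs"`). The decay itself is insensitive to the choice (the
threshold is well inside the converged regime: removing it entirely shifts
T_M by ~2%).

Numerical safeguards in the combination: (i) where the sub-cluster product
in the tilde division falls below 1e-6 in magnitude, the correlation factor
is set to 1 — those points are deep in the decayed region; (ii) an optional
`max_factor` mask replaces |Ṽ_C| > cap by 1. The second guard addresses a
known instability of the truncated expansion: when a strongly coupled pair
signal crosses zero at long delays (possible for near-degenerate pairs with
b ≳ ω), higher-cluster corrections divide by near-zero values and diverge.
Uniform baths at 3-CCE are stable without the mask; baths with molecular
pairing need it for k ≥ 3 at long delays.

Powder averaging uses Lebedev grids (orders 6, 14, 26 with exact rational
weights; default 14). Orientation-dependent excitation efficiency of
rectangular pulses can be supplied as per-orientation weights via the
standard transfer factors ((ω1/ω_eff)·sin(ω_eff t_p) for π/2,
(ω1²/ω_eff²)·sin²(ω_eff t_p/2) for π); the default is ideal pulses
(uniform weights), since a quantitative offset model requires g/A-tensor
parameters that are not part of the synthetic-bath description.

## Linked-cluster analytics

The second-order (in b) term of the refocused echo,

    ⟨V2⟩(τ1,τ2) = − Σ_{m≠n} (2 b_mn²/ω_mn²)(cos ω_mn τ1 − cos ω_mn τ2)²,
    ω_mn = (A_m − A_n)/2,

is implemented as the ordered-pair sum (each unordered pair enters twice).
The prefactor convention was locked empirically: for a single pair with
pseudo-secular terms off, |ln V − ⟨V2⟩| falls by ~1e4 when b is reduced
tenfold (the residual is cubic in b), which is only consistent with the
ordered-sum normalization. The same limit follows from the exact pair
("pseudospin") closed form V = 1 − (ω²b²/ν⁴) sin⁴(ντ), ν² = ω²/4 + b²,
whose small-b expansion equals exp⟨V2⟩ at the Hahn point (τ2 = 0).
⟨V2⟩ ≤ 0 everywhere, vanishes on the Carr–Purcell diagonal τ1 = τ2, and
A_m here is the secular A_zz only. The factorization V = e^⟨V2⟩·f then
defines the residual factor f = V·e^(−⟨V2⟩) (no division hazard since
e^(−⟨V2⟩) ≥ 1); all terms of order ≥ 3 in b, including the cubic one, are
absorbed into f rather than evaluated separately.

Ridge extraction: for each τ2, τ1* = argmax_τ1 V with three-point parabolic
sub-grid refinement, ties broken toward smaller τ1, all-flat slices flagged
and assigned τ1* = 0; the transposed ridge is returned alongside. The
deviation onset is the smallest τ2 from which τ2 − τ1* exceeds a tolerance
(default: one τ1 grid step) persistently to the end of the grid. The
tolerance and persistence rule are implementation choices; published maps
draw the maxima loci without stating an extraction rule.

## Synthetic baths

`generate_bath` places protons volume-uniformly in the shell
[exclusion_e, cutoff] around the electron by seeded hard-sphere rejection
sampling: site count ~ Poisson(density × shell volume), electron exclusion
2.5 Å, H–H minimum 1.5 Å (typical closest-approach distances), thinning by
the protonation fraction. The default density 0.0668 protons/Å³ is that of
pure water; water and 80:20 (v/v) water/glycerol have nearly identical
proton concentrations, so one default covers both matrices. The default
cutoff 12 Å yields ≈ 479 protons — the size regime of a solvated-radical
simulation box.

`generate_solvent_bath` additionally emulates molecular structure: protons
arrive as rigid randomly-oriented units — water dumbbells (H–H 1.51 Å) and
8-proton glycerol units (a frozen MMFF-optimized template, synthetic
stand-in for a real conformer) in the proton-number ratio of the 80:20
glass — with hard-sphere rejection between units. Quantitatively this
matters less than one might expect: intramolecular partners are strongly
coupled (b/2π up to ~18 kHz) but sit at nearly equal distance from the
electron only on average — their hyperfine *difference* is dominated by the
angular factor and is typically 100–300 kHz, so their flip-flops are
moderately suppressed. At 2-CCE the molecular bath shortens T_M by only
~4% relative to the uniform bath of equal density; proton density, not
placement correlation, is the decisive statistic at this level of
description.

What the generator does *not* emulate: the hydrogen-bond network (which
correlates positions and hyperfine values of neighbouring protons),
conformer ensembles, exchangeable vs non-exchangeable protons, and the
radical's own protons. Passing tests on synthetic baths therefore validate
the spin dynamics and the analysis chain, not the fidelity of any
particular solvent's microstructure.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| B0 | 3.38 | T | field; sets ω_I/2π ≈ 143.9 MHz (ESEEM only — the decay is field-independent) |
| density | 0.0668 | Å⁻³ | proton density of water; main determinant of T_M |
| cutoff | 12 | Å | bath radius; protons beyond contribute only slow, late-time dephasing |
| exclusion_e / min_hh | 2.5 / 1.5 | Å | closest-approach radii |
| k | 2 | — | CCE truncation; 2 gives the decay, 3 shifts T_M by ~6%, 4 ≈ 3 |
| threshold | 1580 | Hz | cluster edge criterion (≈ r ≤ 4.24 Å); converged at this value |
| Lebedev order | 14 | — | powder grid |
| fit abscissa | 2τ | s | total evolution time; T_M values are only meaningful with the e^−(2τ/T_M)^x kernel |

## Typical outputs and their interpretation

Under the defaults (uniform fully protonated bath, 2-CCE), the simulated
two-pulse decay fits V0 e^−(2τ/T_M)^x with T_M ≈ 5.0 µs and x ≈ 2.7
(3-CCE: ≈ 4.7 µs); the refocused-echo map shows maxima on the
Carr–Purcell diagonal for τ2 ≲ 1–2 µs that detune to 0 < τ1* < τ2 at
longer τ2, with three-nucleus clusters pushing the maxima substantially
further off the diagonal. These numbers are what the acceptance script and
the test suite recompute.

Measured phase-memory times of real nitroxide samples in protonated
water/glycerol are shorter (≈ 2 µs at low temperature) than the
solvent-bath-only prediction, for two reasons worth keeping apart. First,
experimental decays superpose additional channels excluded here —
instantaneous diffusion, dephasing driven by the radical's own (methyl)
protons — as is evident from fully deuterated solvents, where measured
decays (T_M ≈ 6 µs, x ≈ 0.7) are far from the essentially infinite T_M
this model predicts for an empty proton bath. Second, the synthetic bath
lacks the H-bond-network pair correlations of a simulated molecular glass.
Both effects act in the same direction; the package reports the coherent
solvent-bath contribution alone.

## Numerical choices

* Eigendecomposition (numpy `eigh`, batched) rather than matrix
  exponentials; propagator phases are exact per grid point.
* Cluster Hamiltonians are assembled batched per cluster size from cached
  spin operators; signals are evaluated in chunks of 2048 clusters.
* The tilde combination is evaluated in amplitude space (not log space):
  cluster signals are oscillatory and may legitimately cross zero.
* Stretched-exponential fits use `scipy.optimize.curve_fit` with
  deterministic multi-starts x ∈ {0.8, 1.5, 2.5}, T_M initialized at the
  1/e crossing, bounds x ∈ (0.05, 4]; uncertainties are 1σ from the local
  curvature (covariance) of the objective.
* Degenerate inputs: ω_mn = 0 pairs contribute 0 to ⟨V2⟩ (their continuous
  limit); all-zero map slices are flagged, not divided; empty baths return
  V ≡ 1 with a warning in the CLI.
* Seeds: every stochastic step (bath generation, thinning, noise in tests)
  takes an explicit integer seed; identical seed + parameters give
  identical results bit for bit.

## Known limitations

* Point-dipole hyperfine without Fermi contact; no g/A(¹⁴N) anisotropy in
  the spin dynamics (g enters only the coupling prefactor).
* Ideal pulses; intra-pulse evolution and finite bandwidth are neglected
  (the excitation-weight utility models orientation selection only).
* Partial deuteration as proton removal: correct for the dominant proton
  flip-flop channel, but the ~40× weaker deuteron bath dynamics that
  dominate fully deuterated matrices are absent.
* The truncated expansion can diverge at long delays for strongly coupled
  (molecular-pair) baths at k ≥ 3; the `max_factor` mask is a pragmatic,
  not a principled, remedy there.
* The simulated quantity is the point-echo amplitude; experimental echo
  integration over the echo width is not modelled.
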