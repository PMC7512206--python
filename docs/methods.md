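# Methods

## Data model and block indexing

A spike train is an N × T binary matrix; neuron indices are 1-based, time
offsets 0-based.  An N × L window maps to the integer
ℓ = Σ_{k,n} 2^{nN+k−1} σ_k^n, i.e. bit position nN + (k−1) carries neuron k
at offset n.  This single bit scheme orders every enumeration in the
package: block states, transfer-matrix rows/columns, and monomial labels.
It also makes evaluation cheap — a monomial with mask m is 1 on window w iff
`(w & m) == m`, so potentials evaluate vectorized over all windows.  Readers
reject non-binary rasters rather than clipping; the "at most one spike per
bin" convention is the caller's responsibility upstream.

## Maximum-entropy Markov chains

A potential H of range R (finite coefficients only; no hard-core terms)
induces the transfer matrix L_H over the 2^{ND} block states of memory
D = R − 1: entries e^{H(w)} on transitions whose blocks overlap in D − 1
patterns, 0 otherwise.  Each row has exactly 2^N positive entries and the
matrix is primitive, so the Perron triple (ρ, L, R) exists with ρ simple and
L, R strictly positive.  The chain P(ℓ,ℓ′) = L_H(ℓ,ℓ′)R(ℓ′)/(ρR(ℓ)) with
stationary vector π = L∘R/⟨L,R⟩ is the unique entropy maximizer subject to
the expectations it realizes, and satisfies the variational identity
S(μ) + μ[H] = ln ρ (asserted to 1e−8 on random potentials in the tests).

Range-1 potentials are handled as the memoryless limit: ρ equals the
partition function Z, all other eigenvalues vanish, and every row of P
equals the Boltzmann–Gibbs vector e^{H}/Z.  The closed-form constructor and
the generic spectral route agree to 1e−10 and both are kept, the former as
an independent cross-check of the latter.

Eigensolver: dense (`scipy.linalg.eig`, both orientations) up to 1024
states, power iteration with residual tolerance 1e−12 and a 10^5-iteration
cap beyond.  Internal normalization fixes max(R) = 1 and ⟨L,R⟩ = 1; all
public quantities are invariant under eigenvector rescaling (tested).
Natural logarithms throughout — pressures, entropies and entropy production
are in nats.

## Inference

Constraints are monomial averages C_k, accepted only strictly inside (0,1):
boundary frequencies are unattainable with finite multipliers, and
`from_train` refuses observables whose empirical average is 0 or 1 rather
than returning divergent fits.  The dual g(h) = ln ρ(h) − h·C is smooth and
convex; it is minimized by BFGS with the exact analytic gradient
μ_h[f_k] − C_k (one Perron solve per evaluation), initial point h = 0,
gradient tolerance 1e−8.  K is small at desk scale, so no stochastic
approximation is needed; a soft warning fires for N·R > 20 where the
transfer-matrix route becomes impractical.

Identifiability caveat: the map h → chain is not injective in general.
Potentials differing by a coboundary g(σ¹) − g(σ⁰) + const induce the same
chain, so monomial sets containing single-time-slice pairs (e.g. σ₁⁰
together with σ₁¹) determine only coefficient sums along those flat
directions; the optimizer then returns one valid point of the optimal
affine set, with all expectations still matched.  Cross-temporal monomials
(touching both ends of the window) are free of this aliasing — their masks
are linearly independent of the single-slice span containing every
coboundary — and the recovery tests draw from that class.

## Entropy production

Kolmogorov–Sinai entropy: −Σ πP ln P with 0·ln 0 ≡ 0.  Stationary IEP in
*naive* mode is the pairwise flux formula
½ Σ (J − Jᵀ) ∘ ln(J/Jᵀ), J = diag(π)P, returning +∞ when a one-way pair
carries positive flux; flux pairs below 1e−300 are skipped and detailed
balance is declared below a 1e−10 residual.  The spectral form
Σ (L_ℓ/⟨L,R⟩) L_H(ℓ,ℓ′) (R_ℓ′/ρ) ln[L_ℓR_ℓ′L_H(ℓ,ℓ′)/(L_ℓ′R_ℓL_H(ℓ′,ℓ))]
is algebraically the same quantity (the unpaired sum equals the
½-antisymmetrized one by the flux-pairing bijection) and the two agree to
1e−10 on randomized chains — this equivalence is confirmed numerically, not
assumed.

For memory D ≥ 2 the naive formula diverges *structurally*: overlap-graph
transitions are generically one-way.  The *process* mode instead compares
each transition's flux with the flux of the time-reversed window (reverse
the pattern order inside the length-(D+1) block), which is always an
allowed transition; for D = 1 the two modes coincide exactly.  The
process-mode number is the entropy production rate of the block process as
a trajectory measure and is the package's deliberate extension for longer
memories; it is labeled as such in reports.

The one-step entropy change of a non-stationary distribution ν decomposes
as ΔS = flow + production with
production = ½ Σ (ν_ℓ′P_{ℓ′ℓ} − ν_ℓP_{ℓℓ′}) ln(ν_ℓ′P_{ℓ′ℓ}/ν_ℓP_{ℓℓ′}) ≥ 0
and flow = −Σ ν_ℓ′P_{ℓ′ℓ} ln[ν_{n+1}(ℓ)P_{ℓ′ℓ}/(ν_ℓP_{ℓℓ′})]; note the
flow term's ν_{n+1} argument is the *target* state — the identity
ΔS = flow + production holds to 1e−10 in the tests and pins this down.  At
stationarity ΔS = 0 and flow = −production: the non-equilibrium steady
state.

## Large deviations and the fluctuation relation

For an additive observable f, λ_f(k) = ln ρ(P e^{kf}) with f evaluated per
transition window (for range-1 observables the tilt acts on the source
state; the spectrum, hence λ, is identical to target-side tilting since the
two tilted matrices are similar).  Rate functions are computed by grid
maximization of ks − λ(k) with no closed-form assumption; s-points whose
maximizer lands on a k-grid edge are flagged as boundary rather than
extrapolated.  Default k-grid: [−2, 1] with 301 points, exactly symmetric
about −½ so the Gallavotti–Cohen residual max|λ_W(k) − λ_W(−1−k)| is
evaluated on exact grid mirrors; derivatives at 0 use central differences
with step 1e−5.

The per-transition entropy production matrix F = ln(J/Jᵀ) is antisymmetric
by construction (its off-diagonal entries come in ± pairs); its
flux-weighted mean is the IEP.  One-way transitions make W ill-defined and
raise an error naming the pair.  The empirical W_n is accumulated
incrementally over a trajectory's state sequence and its time reversal
(O(T) total), and W_n/n converges to the IEP; a useful exact finite-n fact,
used in the tests in place of a noisy histogram check, is that
P(W_n = −w) = e^{−w} P(W_n = w) holds identically for stationary chains by
the path-reversal bijection.

## Simulators

*Integrate-and-fire.*  V(t+1) = γV(t)(1−Z[V(t)]) + αW·Z[V(t)] + βI + σ_B·B
with firing indicator Z[x] = 1{x ≥ θ}; a neuron that fires has its leak
term reset.  The associated one-step pattern chain uses firing probability
φ̄((θ − C_i)/σ_B) with drive C_i = γα Σ_j W_ij σ′_j + βI_i and φ̄ the
*normalized* Gaussian survival function — the unnormalized tail would not
yield probabilities.  This memory-1 chain is an approximation of the
voltage dynamics (which retain sub-threshold memory through the leak), so
the sampling cross-check in the tests draws from the matrix chain itself;
the voltage sampler is validated for determinism and limiting behaviour.
Defaults mirror the benchmark conditions: N = 6, γ = 0.2, σ_B = 1, θ = 1,
I_i = 1, W_ij standard normal.

A structural finding worth recording: with all synaptic weights equal the
chain is only *approximately* reversible under the Gaussian escape.  Exact
reversibility of such count-symmetric chains requires the logit of the
firing probability to be affine in the previous spike count; the Gaussian
tail's logit is not (residual IEP ~1e−9…1e−4 depending on N and the weight
scale), whereas the kinetic Ising logistic is affine, making the analogous
identical-couplings kinetic chain exactly reversible.  The test suite
asserts the idealized claim for the IF model and the corresponding test is
expected to fail by that margin; the kinetic-Ising counterpart passes at
1e−10.

*Kinetic Ising.*  P[σ′|σ] = Π_i e^{(2σ′_i−1)θ_i(σ)}/(2cosh θ_i(σ)) with
θ_i(σ) = βh_i + αΣ_j J_ij(2σ_j−1).  (A `strict_as_printed` switch replaces
the coupling sum's σ_j by σ_i, reproducing a self-referential variant that
circulates in transcription; it is kept for auditability only.)  Scan
defaults: h_i ~ N(−3, 1), J_ij ~ N(0, 1), N = 6, 500 realizations per grid
cell (tests and examples use ≤ 25 and N = 4 to keep runtimes in seconds;
the structure — zero at α = 0, positive for generic asymmetric couplings —
is unchanged at that scale).

*One-step pairwise ensemble.*  For fixed fields and synchronous couplings,
γ matrices are drawn from N(mean, sd²), optionally (anti)symmetrized; each
draw yields a range-2 potential, its chain, and its IEP.  Symmetric γ gives
detailed balance (IEP < 1e−8 across draws); γ = 0 recovers the reversible
synchronous pairwise model; generic asymmetric draws are strictly
irreversible.  The double coupling sum includes the diagonal, contributing
J_ii/2 to the field on σ_i since σ² = σ; the temporal term couples neuron i
at time 0 to neuron j at time 1.

## What the synthetic data do and do not show

Samplers draw the initial block from π and successive patterns from the
chain rows, so sampled rasters are exactly stationary and Markov of the
declared memory.  Real recordings are neither: they are non-stationary,
have refractory structure, and their generating process is not finite-range.
Passing recovery tests therefore demonstrate correctness of the estimator
under its own assumptions, not adequacy of those assumptions for any
particular tissue.  Problem sizes used in the tests — N ≤ 6, R ≤ 3,
T ≤ 10^6, ensembles of 20–25 draws — are desk-scale choices keeping the
whole suite under a minute; all formulas are exact in the state-space size,
so larger N trades time, not accuracy, up to the N·R ≤ 20 practical limit.

## Known limitations

- Dense transfer matrices: memory and time grow as 4^{ND}; no sparse or
  Monte-Carlo path is provided beyond the soft N·R ≤ 20 warning.
- Naive IEP is +∞ for D ≥ 2 by construction; the process mode is the
  package's extension and should be cited as such.
- Boundary or inconsistent constraint sets are rejected, not regularized.
- The CLI covers single runs and scans; no plotting is included.
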