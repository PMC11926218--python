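# Methods

Model assumptions, parameter defaults and numerical choices behind the
`slidepull` package. Units throughout: nm, pN, s, K; thermal energy
`k_BT = 0.0138…·T pN·nm` (4.114 pN·nm at 298 K).

## Worm-like chain elasticity (`slidepull.wlc`)

Force law (interpolation formula):

    F(z) = (k_BT / L_p) · [ ¼(1 − z/L_c)⁻² + z/L_c − ¼ ]

- Defined on `0 ≤ z < L_c`; calls outside the domain raise rather than
  clamp, because the divergence at `z = L_c` is physical.
- F is linear in `1/L_p`, so `n` identical chains in parallel respond
  exactly like one chain with `L_p,eff = L_p/n` and the same `L_c`.
  Two parallel 4.1 nm segments therefore fit as a single chain with
  `L_p,eff = 2.05` nm — this is target t2 and is exact, not asymptotic.
- `wlc_extension` inverts the force law by bracketed root finding
  (`brentq` on `[0, L_c(1−1e−9)]`); `wlc_stiffness` is the analytic
  derivative, used for instantaneous loading rates.
- `fit_wlc` is an unweighted least-squares fit (`scipy.least_squares`)
  with `L_c` bounded below by the largest extension; degenerate inputs
  (all-zero force) and optimizer failures return `converged=False`
  with a message, never a silent success. Single-chain HA persistence
  length default: 4.1 nm.

## Pulling simulator (`slidepull.simulator`)

Fixed-time-step kinetic Monte Carlo of an AFM tip retracting at
constant velocity `v` from a surface on which `n` receptors engage one
polysaccharide chain.

Common geometry: receptors clamp the chain at contour "registers"
measured from the tip anchor, spaced `d_rms = 20` nm apart; the tip
force is the WLC tension of the tip→innermost-register segment; tension
beyond the outermost engaged receptor is zero.

**Sliding mode.** The chain hops through each engaged receptor in
steps of one disaccharide `δ = 1.0` nm with zero-force rate
`k = 10³ s⁻¹` in both directions. The total tension drop is shared
equally across the `m` engaged receptors, so each hop is biased by
`ΔT = F_tip/m` over a barrier at `δ_b` (default `δ/2`, symmetric):
rates `k·exp(±ΔT·δ_b/k_BT)`. Hops that would reorder registers are
rejected (the chain is a single file); a receptor disengages
permanently when its register reaches the chain contour (the free end
passes through). Balancing the net hop flux against the imposed speed
gives the analytic plateau per receptor:

    f = (2 k_BT/δ) · asinh( v / (2 k δ) )  = 3.96 pN at study conditions,

so `n = 5` receptors give ≈ 19.8 pN. The sampled plateau
(median force over the full-engagement window) runs ~12% above this
because the WLC tether is finitely extensible (the chain must slide
faster than the tip by the factor `1/x`, `x = z/L_c ≈ 0.89` at plateau
tension) and because single-file blocking slightly reduces mobility.
The median *peak* force over 50 seeds is ≈ 27.9 pN — below the 30 pN
scale (target t3).

**Initial engagement (`threading_depth`).** At the start of retraction
a contour length `threading_depth` (default `chain_contour/2`) has
already passed beyond the outermost receptor, consistent with the
end-on threading picture: the free end docks first and the chain
threads through the serial receptors during the surface dwell. This
matters: if the registers started near the free end, zero-force hopping
at `10³ s⁻¹` would carry them off the chain during the slack phase of
retraction and no tension plateau could develop.

**Sticking mode.** Each receptor holds its register fixed; the
innermost engaged bond carries the WLC load and ruptures with the Bell
rate `k_off·exp(F·x_β/k_BT)` (defaults `k_off = 0.6 s⁻¹`,
`x_β = 0.4` nm), integrated as a hazard on the sampling grid against an
exponential threshold. The retract curve is a sawtooth of sequential
ruptures at 30–60 pN — the qualitative contrast to sliding.

**Numerics.** The fixed step `τ` is sized so the per-step hop
probability stays below 0.1 even at 3× the steady-state bias;
user-supplied steps that could violate the cap are rejected. All
randomness flows from one `numpy` generator per seed; a given
`(config, seed)` is bit-reproducible.

## Force-curve analysis (`slidepull.curves`)

- On-disk format: one UTF-8 TSV per curve (`time_s`, `distance_nm`,
  `force_pN`, printed with `%.17g`) plus a JSON sidecar with velocity,
  spring constant, temperature and segment. Write→read round trips are
  bit-identical (`float_precision="round_trip"` on read).
- Baseline: linear fit to the final 10% of the retract (far from the
  surface), subtracted.
- Event detection: median-filtered force; a candidate is a local
  maximum followed by a drop ≥ 10 pN (≈5× thermal noise) completed
  within 15 nm. Events at tip–substrate distance ≤ 250 nm are
  discarded — the minimum-distance filter that suppresses non-specific
  tip–sample adhesion and keeps `L_c ≫ L_p` for the fits.
- Each event's preceding stretch (from where the force last rose above
  20% of the rupture force) is WLC-fitted; the instantaneous loading
  rate is `r = k_eff·v` with `k_eff` the fit slope at rupture.
  Unconverged fits exclude the event rather than contaminate spectra.
- Loop sizes: 1-D k-means on effective contour lengths, `k` chosen by
  silhouette (threshold 0.65, below which the result is flagged and
  collapsed to one cluster).
- Bell–Evans fit: rupture forces are binned in log-spaced loading-rate
  bins (4 per decade); the model
  `F*(r) = (k_BT/x_β)·ln(r·x_β/(k_off·k_BT))`, linear in `ln r`, is
  fitted to bin means and the (k_off, x_β) covariance propagated by the
  delta method. Events must span ≥ 1 decade of loading rate.
  Note: `F*(r)` is the *most probable* rupture force; fitting it to
  sample *means* leaves `x_β` unbiased but overestimates `k_off` by a
  systematic factor ≈ e^γ ≈ 1.78 (γ = Euler–Mascheroni), since the
  mean exceeds the mode by ≈ γ·k_BT/x_β. The exact mean under a
  constant ramp is `f_β·e^α·E1(α)` with `f_β = k_BT/x_β`,
  `α = k_off·f_β/r` (`slidepull.synth.bell_mean_rupture_force`), and
  the tests use it as the simulator oracle.

## Binding kinetics (`slidepull.kinetics`)

End-on capture of a coil of radius `R_g` (default 75 nm) on a receptor
lawn of rms spacing `d_rms` approached at `v`:

    c_end = ((4/3)πR_g³·N_A)⁻¹,  N_R = πR_g²/d_rms²,  t_b = 2R_g/v
    k_on ≥ (N_R·c_end·t_b)⁻¹ = (2/3)·d_rms²·N_A·v

`R_g` cancels exactly (the composite and closed forms agree to machine
precision); at `d_rms = 20` nm, `v = 1` μm/s the bound is
1.61×10⁵ M⁻¹s⁻¹. Side-on (loop) binding uses first-order occupancy
kinetics `k_on = −ln(1−P)/(c·t)`; `P = 1` is saturated and rejected,
`P = 0` returns a zero-rate sentinel. `K_D = k_off/k_on`.

## Structural analyses (`slidepull.structure`)

- Superposition: Kabsch/SVD with the determinant correction (proper
  rotations only); collinear point sets are rejected as non-unique.
  Cα pairing across structures by residue number or by global sequence
  alignment (Biopython PairwiseAligner) for renumbered/deleted
  residues.
- Hydrogen bonds: donor–acceptor distance ≤ 3.6 Å; when hydrogens are
  present (MD mode) the acceptor⋯H–donor angle must lie in 120–180°
  and the donor must actually carry a hydrogen. Without hydrogens
  (crystal mode) the distance criterion alone applies;
  `require_hydrogens=True` raises with guidance instead of silently
  falling back. Donor/acceptor assignment covers standard amino acids
  (backbone N + classical side-chain donors), water, and — for
  non-standard residues such as the HA sugars — every O/N.
- Bridging waters: a water bridges in a frame when simultaneously
  H-bonded to ≥ 1 protein and ≥ 1 ligand atom; the order is the number
  of simultaneous partners (2 binary, 3 ternary, ≥ 4 quaternary); the
  total occupancy sums orders whose individual occupancy reaches the
  10% minimum component.
- RMSF: frames are iteratively superposed on an alignment selection
  onto the running mean (3 iterations); per-residue RMSF is the rms
  heavy-atom fluctuation. `rmsf_ratio` gives apo/complex
  rigidification ratios, excluding zero-denominator residues.
- PDB (single- and multi-model for trajectories) is read/written via
  gemmi at the file boundary only.

## Synthetic data (`slidepull.synth`)

Every pipeline input can be generated with known ground truth: WLC
stretch-and-rupture curves (including parallel loop segments and
multi-event sawtooths) with Gaussian noise/drift; Bell rupture samples
drawn exactly by inverse transform of the first-passage distribution
(independent of the time-stepping simulator they validate); toy
trajectories with planted contact occupancies (exact frame fractions),
bridging waters of specified order, and per-residue fluctuations, each
feature in its own spatial site so detections cannot cross-talk; and
structure pairs under a known rigid transform plus Gaussian
perturbation (expected RMSD ≈ √3·σ).

## Scope and limitations

- The sliding model is deliberately reductionist: equal tension
  sharing, a single hop barrier, no receptor re-engagement, no chain
  elasticity between receptors. It reproduces force *scales*, not
  instrument traces.
- Crystal-structure comparisons (cross-species Cα RMSD, deposited
  H-bond counts) require downloading deposited coordinates; the
  machinery is fully implemented and verified on synthetic structures,
  but those literature numbers are not recomputed offline.
- Experimental magnitudes that depend on instrument data (absolute
  rupture-force distributions, measured k_on) are covered qualitatively
  (mode contrast, order-of-magnitude checks), not as numeric targets.
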