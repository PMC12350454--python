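# Methods

This note records the models, conventions and numerical choices behind
`bindscape`, and what the synthetic benchmarks do and do not establish.

## Units and conventions

Lengths are Å, times ps, energies kcal/mol, charges elementary charges,
masses amu; conversions happen only at I/O edges. Frame and atom indices
are 0-based internally (PDB serials are 1-based in files only). Residue
identity is the pair (segment, residue id); insertion codes are rejected.
The ligand is whatever the JSON topology tags `"ligand"` — explicit
tagging beats HETATM heuristics. k_B = 0.0019872041 kcal/(mol K); the
default temperature is 310 K, so kT = 0.61603 kcal/mol. The Coulomb
prefactor is 332.0716 kcal Å/(mol e²) and the GB prefactor half of it.

## Superposition and stability metrics

All fits are weighted least-squares rigid superpositions (Kabsch via an
SVD-backed rotation solver); the residual is recomputed from the
transformed coordinates, because the solver's own residual loses
precision near zero. Fits require ≥ 3 non-collinear points. Protein RMSD
uses the bead/Cα set, mass-weighted. Ligand RMSD is measured *after*
fitting on the protein only — no re-fit on the ligand — so it reflects
pose change in the pocket, which is what the landscape axis needs. RMSF
and PCA superpose each frame onto the iteratively converged mean
structure (fit → new mean, until the mean shifts < 1e-6 Å, ≤ 10
rounds). "Most stable replica" means minimal variance (not minimal mean)
of the protein RMSD over the final window: stability is about
fluctuation, not offset. The reference structure defaults to frame 0.

## Free-energy landscape and crucial interval

The landscape is a plain 2-D histogram over [min, max] per axis
(default 50 bins per axis, exposed as config) converted with
G = −kT ln(P/P_max). Unsampled bins carry +inf, never 0: −kT ln 0 is
undefined and a zero would fabricate a global minimum. The ground basin
is a 4-neighborhood flood fill from the global-minimum bin over bins
with G ≤ cutoff; the default cutoff of 1 kT captures the minimum's
neighborhood without merging wells. Exact ties between global minima are
broken toward the lexicographically lowest bin and logged. The crucial
interval maximizes the in-basin count over a fixed-length window
(default 100 frames, the "1 ns at 10 ps/frame" convention; both window
and spacing are explicit config because saved-frame spacing is an input,
never guessed). Ties take the earliest window; the representative frame
is the in-basin frame nearest (start + end − 1)/2, ties toward the lower
index.

## Essential dynamics

PCA diagonalizes the 3N×3N covariance of site fluctuations after the
iterative-mean alignment (alignment can be disabled for selections too
small to superpose). Rank deficiency (3N > frames) is allowed and
logged; the eigenbasis is still complete, which is what makes the
"PC-filter with all modes equals the direct matrix" identity exact. The
DCCM uses one site per residue (its first selected atom) and fluctuations
about the window mean *as given*: removing global rigid motion
necessarily redistributes correlation between regions (fitting out the
common displacement of two coherent blocks makes them anti-correlated),
so superposition is the caller's explicit choice (`align=True`) rather
than a hidden default. Zero-variance sites get NaN sentinel rows —
"undefined" is a different statement from "uncorrelated". The default
PC subset for filtered matrices is the smallest k explaining ≥ 50% of
the variance.

## MM/GBSA

Single-trajectory protocol: receptor and ligand conformations are
extracted from complex frames, so intramolecular bonded terms cancel
exactly and only intermolecular MM terms plus the solvation change
survive. Electrostatics is screened Coulomb (eps_in = 1); vdW is 12-6
LJ in the Rmin/2–epsilon convention with Lorentz–Berthelot combination
and no cutoff (the systems analysed here are small; engine-side cutoffs
belong upstream). Polar solvation is generalized Born with Still's
interpolation f_GB = √(r² + R_iR_j exp(−r²/4R_iR_j)) and self terms
f = R_i, eps_out = 78.5, no salt. Effective radii follow the HCT
pairwise-descreening scheme with intrinsic radii reduced by 0.09 Å; the
descreening integral is evaluated in closed form (derived from the
spherical-cap antiderivative and verified against numerical quadrature
in the tests), radii floored at half the reduced radius (logged), and a
fixed-radii mode (effective = intrinsic) exists for closed-form checks.
The nonpolar term is γ·SASA with γ = 0.0072 kcal/(mol Å²), β = 0, probe
1.4 Å; SASA is Shrake–Rupley on a deterministic Fibonacci sphere
lattice (default 960 points; fewer than 24 is refused). Points exactly
on a neighbor's surface — coincident spheres — are assigned to the lower
atom index, so two coincident atoms expose exactly one sphere.

Per-residue decomposition splits every intermolecular pair term 50/50
between the partners, assigns each atom its row of the GB pair matrix
(cross terms 50/50, self terms whole) differenced between complex and
isolated states, and distributes the surface term by per-atom ΔSASA.
These shares re-add to the binding total exactly per frame, which the
tests assert to 1e-6 and the implementation achieves to ~1e-14. Reported
mean ± sd uses the population standard deviation over frames. No
entropy term is computed.

## Interaction typing

Hydrogen bond: donor–acceptor distance ≤ 3.5 Å and donor–H–acceptor
angle ≥ 135°; contact: minimum interatomic distance ≤ Rmin/2 sums
+ 0.5 Å; π-stacking: ring-centroid distance ≤ 5.5 Å and interplanar
angle ≤ 30° with normals from each ring's best-fit (SVD) plane. All
thresholds are config; these defaults are conventional geometric
criteria. Topologies carry no bonds, so each polar hydrogen is paired
with the nearest donor-heavy atom within its own residue in the frame
under evaluation. Fingerprint diffs report interactions above an
occupancy floor (default 0.5) present in exactly one system, plus
hydrogen-bond/π-stack ↔ contact type switches for shared partners.

## Synthetic benchmarks

`build_toy_complex` makes a Cα-like bead chain (3.8 Å spacing) bent
around a concave pocket with a gentle out-of-plane wave (so fits are
well-conditioned), plus a small ligand with a six-bead planar ring, a
donor/H/acceptor triple, zero net charge per molecule, and plausible
LJ/GB parameters (intrinsic Born radii 1.2–2.0 Å).

`simulate_two_basin` runs overdamped Euler–Maruyama Langevin dynamics,
x ← x − U′(x)Δt/γ + √(2kTΔt/γ)·η, on a tilted quartic double well in
the ligand–anchor distance (minima 6 and 10 Å, barrier 3 kcal/mol above
the lower well, 1 kcal/mol offset between wells; barrier 0 degenerates
to a single harmonic well). Friction is fixed at γ = 1 ps⁻¹·amu-equiv.
Frames are saved every 10 ps while the integrator steps at 0.025 ps:
the substeps decorrelate successive frames (each saved frame is ~400
integration steps, giving hundreds of barrier crossings per 5·10⁴
frames) and keep the O(Δt) discretization bias of the stationary law
well below the test tolerances — a single-step-per-frame walk at any
step size fails one of the two requirements. A stability pre-check
refuses integration steps whose drift exceeds the well separation
anywhere in the thermally accessible region. The second CV is a
deterministic curved embedding of the first (linear trend + sinusoidal
modulation), which keeps the binned image of the 1-D process 4-connected
instead of collapsing to a bare diagonal. The exact potential is
returned, and the Boltzmann oracles (occupancy ratio, per-bin expected
weights) integrate it by quadrature rather than trusting the
exp(−ΔU/kT) shorthand, which the tilt makes slightly inexact. The FEL
RMS comparison is restricted to well-sampled bins (count ≥ 25), where
the histogram estimate of G is not shot-noise dominated.

`simulate_block_correlated` draws per-frame, per-residue displacements
from a zero-mean Gaussian whose site correlation is ρ_in within
contiguous residue blocks and ρ_out across (eigen-based square root;
non-PSD parameter combinations are refused before sampling), isotropic
per axis, applied to every atom of the residue. In the two-basin
generator, a `coupling` factor scales *all* off-diagonal correlations by
(1 − coupling) while the ligand occupies the second basin — both the
intra- and inter-region coherence drop in the "bound-destabilized"
condition, which is the property the comparative DCCM analysis detects.

What passing these benchmarks shows: the statistical machinery (FEL
inversion, basin/interval logic, DCCM normalization, energy identities)
is correct against analytically known truth. What it does not show: the
toy beads have no secondary structure, no explicit solvent history, no
conformational gating, and interaction occupancies far sparser than a
real pocket, so agreement here does not certify force-field-level
realism on protein-scale inputs.

## Determinism and I/O

Every generator is a pure function of its spec and one integer seed (a
`numpy` Generator; no global RNG state). DCD is the CHARMM little-endian
dialect without fixed atoms, written and read through MDAnalysis' DCD
layer; coordinates are cast to float32 on write, so write→read→write
round trips are byte-identical. PDB passes through biotite with a
fixed-column pre-scan that names the offending line and rejects
insertion codes; the one-character chain column carries the first letter
of the segment tag, and authoritative segment tags travel in the JSON
topology. Pipeline outputs embed the package version, a hash of the
scientific configuration (the output directory is excluded from the
hash) and the seed; reruns with identical config and seed are
byte-identical, which the acceptance checks assert by digest.

## Problem sizes used in the checks

The statistical checks run at the sizes their tolerances are calibrated
for: 5·10⁴ frames for Boltzmann/landscape recovery (±15% occupancy,
RMS ≤ 0.3 kcal/mol), 5·10³ frames for DCCM recovery (±0.05), 10³ random
series of length 2·10³ for the crucial-interval oracle, and a 400-frame
toy run for full-pipeline determinism. The whole suite and the
acceptance script each finish in well under a minute of compute apiece.
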