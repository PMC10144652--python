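# Methods

## The model

The package post-processes classical MD trajectories to obtain electronic
circular dichroism (ECD) and UV absorption spectra of a solvated chromophore
by the perturbed matrix method (PMM). The chromophore is the *quantum
center* (QC): its gas-phase electronic structure — state energies `E_l^0`,
electric-dipole matrices `mu_p^0` and magnetic-dipole matrices `m_p^0`
expressed in the unperturbed eigenstate basis — is computed once per
reference conformation by an external quantum-chemistry code and consumed
here as a structured file. At every MD frame the environment point charges
generate an electrostatic potential `V(r0)` and field `E(r0)` at the QC
center of mass `r0`, and the perturbed electronic Hamiltonian is built in
the unperturbed basis as

    H = diag(E^0) + q_tot V(r0) I − E(r0) · mu^0 .

This is the exact matrix form of the multipolar expansion of the
perturbation truncated at dipole order: the sum of `q_n [V(r0) − E(r0)·(r_n
− r0)]` over all QC particles (nuclei *and* electrons) collapses to the net
charge times the potential (on the identity) plus the field contracted with
the dipole operator, whose matrix elements over the electronic states are
exactly the `mu_p^0` matrices with the nuclear contribution included.
Diagonalizing `H` gives perturbed states `c_i`; transition dipoles follow by
congruence, `mu_ij = c_i† mu^0 c_j` and `m_ij = c_i† m^0 c_j`, and the
rotational strength of each ground-to-k transition is

    R_k = Im{ mu_0k · m_0k } ,

converted to cgs with the standard atomic-unit factor 471.44e-40
(e·a0 for the electric and e·hbar/(m_e c) for the magnetic dipole).

Assumptions inherited from this level of theory: the perturbing field is
homogeneous over the QC (dipole truncation — adequate for monosaccharide-
sized QCs, inaccurate for large ones); the environment is purely
electrostatic fixed point charges (no polarization or QC back-reaction);
transitions are vertical (no vibronic structure); state identity per frame
is defined by energy ordering (no diabatic tracking — the spectrum sums
only need ground-to-k energies and strengths per frame).

## Spectra

Per transition k, the vertical excitation wavenumbers collected over the
trajectory are histogrammed into bins of width `bin_width` (default
200 cm⁻¹, edges aligned to integer multiples so binning is order- and
batch-independent). Each occupied bin with middle value `nu_ref`, frame
count `n` and bin-mean rotational strength `<R_k>` contributes

    d_eps_0k(nu) = <R_k> · nu / 2.296e-39 · (n/N)
                   · exp(−(nu−nu_ref)² / 2σ²) / sqrt(2πσ²)

and the molar CD spectrum is the sum over bins and transitions. The
Gaussian (unit-normalized; width `σ`, default the wavenumber equivalent of
0.15 eV) stands in for the classical vibrational broadening the vertical
picture discards; `σ` is a direct user input, not estimated here. The
constant 2.296e-39 is the standard cgs conversion between rotational
strength and the `d_eps/nu` integral, which fixes the normalization choice:
the package's area identity

    ∫ d_eps_0k/nu d nu = Σ_bins <R_k> n / (N · 2.296e-39)

holds to quadrature accuracy independently of σ, and is enforced by test.
The UV analogue replaces `<R_k>` with the bin-mean dipole strength
`<|mu_0k|²>` and the prefactor with the companion constant 9.184e-39
(= 4 × 2.296e-39), the standard cgs dipole-strength extinction relation.
Curves are evaluated on a wavenumber grid and reported with a wavelength
axis; the default reporting window is 160–220 nm, the experimentally
sampled far-UV domain for carbohydrates.

Conformer spectra are combined as pointwise convex sums with the conformer
probabilities, then anomer spectra with the experimental alpha:beta
population ratio (glucose 32:68, galactose 38:62, shipped as data). A
per-transition report lists the maximum band intensity of each transition,
keeping those above a floor of 1.0 M⁻¹cm⁻¹.

## Essential-dynamics conformational analysis

The free-chromophore trajectory is mass-weighted rigid-body fitted
(Kabsch superposition, via `scipy.spatial.transform.Rotation`) to a
reference structure — the first frame by default. The 3N-coordinate
covariance matrix is diagonalized; eigenvalues are per-mode mean-squared
fluctuations (nm²) and the top two eigenvectors span the essential plane.
Projected frames are histogrammed on a 60×60 grid over the sampled range
(±5% padding) and converted to a Helmholtz free-energy surface
`dA = −k_B T ln(P/P_max)` with `k_B = 0.0083145 kJ/mol/K` and T = 300 K by
default. Unsampled cells carry NaN plus an explicit mask, never a number.

Basins are found by a flooding watershed over sampled cells in order of
increasing `dA`: a cell with no labelled neighbor (8-connectivity) seeds a
basin; a cell bridging several basins merges any basin shallower than
`basin_threshold` (default 3 kJ/mol) below the bridge into the deepest, so
every surviving basin is at least that deep. Catchments holding less than
`min_basin_occupancy` of the frames (default 1%) are discarded as sampling
noise. Reference configurations (RCs) are allocated to basins
proportionally to catchment occupancy with every basin receiving at least
one; within a basin the RC cells are the lowest-free-energy cells, each RC
is the trajectory frame nearest its cell center in the essential plane, and
RC probabilities are catchment occupancies partitioned by nearest RC cell
and renormalized to one. Summing probabilities over full catchments (rather
than threshold-trimmed cores) keeps them unbiased estimates of basin
Boltzmann weights.

Dihedrals use the standard IUPAC sign convention (verified against
MDAnalysis), reported in [0°, 360°); per-cell means are circular, since the
GG class spans 60° and 240° and arithmetic means corrupt wrap-around maps.
The hydroxymethyl rotamer classifier is nearest-center on the circle — TG
at 0°, GG at 60°/240°, GT at 180° — with boundaries at the circular
midpoints 30°, 120°, 210°, 300°.

## Synthetic data

The fixture generators define the test conditions; all are driven by one
integer seed and bit-reproducible.

* **Electronic sets**: ascending energies with the lowest vertical
  excitation pinned at 6.5 eV (UV onset just above 190 nm, giving the
  far-UV red-tail shape typical of sugars) and 17 states by default;
  random symmetric electric-dipole and purely imaginary antisymmetric
  magnetic-dipole matrices at a 0.5 a.u. scale.
* **Solvent frames**: 951 neutral three-charge groups (−2q, +q, +q with
  q = 0.41 e, SPC-like magnitudes) in a spherical shell of 0.65–1.3 nm
  around the QC, emulating the first solvation shells of a small solute in
  a ~2 nm water box. The two positive charges sit at symmetric ± offsets,
  so each group is dipole-free: frames are exactly neutral, the far field
  decays as a quadrupole, and the randomized placement still yields
  solvent-scale field fluctuations (~1e-2 a.u.) at the QC.
* **Conformational trajectories**: a 10-atom chain with one soft torsion
  drawn from a mixture of von Mises basins (default GG:GT = 60:40 at
  centers 60°/180°, matching the beta-glucose rotamer split), stiff-mode
  jitter on the remaining torsions, and random rigid-body motion; true
  per-frame basin labels are returned for recovery tests.

What the generators do *not* emulate: real water structure and hydrogen
bonding, force-field energetics, intramolecular couplings beyond one soft
torsion, or the actual sugar electronic structure. Passing tests therefore
demonstrate the correctness of the machinery — Coulomb sums, matrix
construction, eigen-solvers, binning, weighting, statistics — not the
accuracy of any particular force field or functional on real
monosaccharides.

## Numerical choices

* Internal units: Hartree/atomic units for everything electronic, nm for
  coordinates (converted to bohr inside Coulomb sums), cm⁻¹ for spectra.
  File formats carry explicit unit headers; energies are converted on load.
* Eigenvector phase fixed deterministically: the largest-magnitude
  component of each eigenvector is made real-positive (ties break to the
  lowest index), so transition dipoles are reproducible bit-for-bit.
* Magnetic-dipole matrices are stored as complex though physically purely
  imaginary; validation requires them purely imaginary and antisymmetric
  (the Hermitian matrix of an imaginary-valued Hermitian operator in a real
  basis), electric-dipole matrices real symmetric, both at 1e-8 relative
  tolerance.
* Environment points closer than 0.05 nm to the QC center of mass abort
  the frame (clash/overlap artifact) unless a permissive flag skips and
  logs it. Coulomb sums are direct O(N) with no cutoff.
* Degenerate perturbed states keep their eigenvalue-sort order; their
  strengths merge naturally in the same spectral bin.
* Trajectory processing is streaming: memory use is independent of
  trajectory length, for both PMM records and spectrum binning.

Default problem sizes in the shipped pipeline configuration (2000
conformational frames, 200 environment frames per RC, 60×60 landscape
grids, 1e5 samples in statistical recovery checks) were chosen so that
statistical estimates sit well inside their tolerances while a full run
completes in seconds on a laptop.

## Known limitations

* Dipole-order truncation only; no quadrupole or higher PMM orders.
* No vibronic coupling; band shapes come entirely from the classical
  broadening kernel, so fine structure is out of reach.
* No diabatic state tracking: if perturbed states cross between frames,
  per-transition (but not total) spectra can mix character.
* Basin detection is grid-based; basins narrower than a cell or split by
  sampling gaps are at the mercy of the histogram resolution.
* The absolute rotational-strength scale assumes Gaussian-convention
  atomic units for the magnetic dipole input; a source using Bohr-magneton
  units must be converted at the file boundary.
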