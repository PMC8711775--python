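# Methods

`helmetspect` simulates a stationary brain-SPECT scanner built from ~500
micro-camera elements (MCEs): compact pixelated CZT modules, each behind a
single strongly minifying tungsten aperture, packed on a helmet-shaped
spherical support so that every camera views the same 20-cm spherical
field of view (FOV). The package constructs the geometry, traces the
system response matrix (SRM), simulates acquisitions of digital phantoms,
reconstructs them with OSEM, and evaluates designs with Fisher-information
and image-quality metrics. This note records the model, its assumptions,
and the numerical and design choices.

## Helmet geometry

502 MCEs are arranged in 18 rings plus a top-cover module: 345 in the
hemispherical section (11 full rings and the pole module) and 157 in a
neck section of 7 half-rings spanning 180° of azimuth, leaving a frontal
opening for the face. Every camera axis points at the FOV centre. The
aperture planes are tangent to a sphere of radius `D_a = 183.23` mm and
the detector entrance faces sit `f = D_a/12 ≈ 15.269` mm behind them,
fixing the 1:12 minification exactly. The separately quoted 196-mm
support radius is treated as a nominal mechanical figure: it is mutually
inconsistent with the `D_a`/minification pair (which would put the
detector at ≈198.5 mm), and the optical pair is what determines every
computed quantity, so it wins. The published per-ring module counts are
not publicly available; the default layout distributes modules over rings
proportionally to ring circumference (deterministically rounded) and is
overridable via `ring_counts` should the published layout surface.
Adjacent full rings are offset by half an angular pitch so trans-axial
views interleave.

World frame: right-handed, origin at the FOV centre, +z craniocaudal
(toward the vertex), +y ventro-dorsal (toward the occiput, so the frontal
neck opening faces −y), +x lateral. Configs take degrees; internals use
radians.

## Aperture solids

Each aperture is a 20-mm tungsten slab (`t_u` above / `t_l` below the
aperture plane) minus an open channel that pinches to the nominal opening
exactly at the plane and flares toward the object with acceptance
half-angle(s) α and toward the detector with exit half-angle(s) β, both
measured from the camera axis:

* **lofthole** — circular opening of diameter `d`, lofted into square
  cross-sections at the slab faces (the gauge interpolates linearly
  between the L2 and L∞ norms with depth), so projections tile the square
  detector while the open area stays `πd²/4`;
* **micro-slit** — rectangular opening `w × l` (l/w ≥ 10) with
  independent α/β per direction; the opening and object-side profile are
  rotated by the per-camera angle θ while the detector-side profile stays
  squared to the module footprint. The helmet assigns the 502 rotations
  as a seeded random permutation of {k·360°/502} (increment ≈ 0.717°);
* **micro-ring** — annular opening between a flared outer piece and a
  central plug of maximum radius `r_i` that tapers away from the plane in
  both directions; the plug is thick enough (≥ 10 mm axially) to absorb
  axial photons.

Default parameter sets: loftholes of 0.5/1/1.5/3-mm diameter with
α = 27.3°, β = 29.4° (t_u/t_l split 11/9 mm — the split is not published
for loftholes; the slit's 9/11 split mirrored about the plane is used and
is configurable); slits 250 µm × 5 mm and 150 µm × 6 mm with
α_short = 27.3°, β_short = 29.4°, α_long = 35.3°, β_long = 22.6°/21.1°,
t_u/t_l = 9/11 mm; micro-ring with r_o = 3.75 mm, r_i = 3.5 mm
(α = 36.3°, β = 32.7°, t_u/t_l = 7/13 mm). The ring radii deserve a
flag: the literature for this design states both an outer radius of
7.5 mm and an open area of 5.69 mm²; these cannot both hold for a 250-µm
annulus. The area-consistent reading (r_o = 3.75 mm) is the default
here; the radii are plain constructor arguments, so the alternative is a
one-line change. The "combined 3-type" collimator cycles 0.5/1.5/3-mm
loftholes along the ring-ordered MCE sequence (168/167/167 of each), so
neighbours within a ring always differ.

Tungsten attenuation µ_w defaults to a NIST-derived log-log interpolation
(3.64 mm⁻¹ at 140 keV, valid 80–300 keV) and is overridable; CZT uses
0.354 mm⁻¹ at 140 keV.

**Ray transmission** is Beer–Lambert over the tungsten chord length,
estimated by fixed-step midpoint ray marching (default 25 µm), which is
uniform across aperture kinds and whose error is bounded by a few march
steps per material boundary; the test suite bounds it against a 5-µm
march. Rays with exactly zero chord are *signal*, partially attenuated
rays are *noise*, rays below a transmission floor are *blocked*. Two
accelerations keep full-helmet traces desk-scale without changing
results beyond the stated floors: a provable geometric prune (a ray
whose aperture-plane crossing lies farther than
`x_cut·(1+tan α_max)/2·1.3` from the opening cannot have a chord below
the cutoff, because the channel is pinched at the plane and the gauge is
1-Lipschitz), and an optional transition-refined march (coarse 0.25-mm
cells, re-marched finely around material transitions, near the waist and
at the slab faces) used for SRM assembly; classification-sensitive paths
(aperture SNR) always use the plain fine march.

## System response matrix

Element `a_mn` is the probability that a photon emitted isotropically in
voxel `n` is recorded in bin `m = (MCE, pixel i, pixel j, DOI layer k)`.
One ray is traced per (voxel, pixel) pair, from the voxel centre to the
pixel centre at mid-crystal depth, and

    a = ΔΩ_pix/(4π) · T_aperture · P_k · T_object

with `ΔΩ_pix = A_pix·cosγ/dist²` evaluated at the detector entrance
face, `P_k = e^(−µ_czt·c_k,before)·(1 − e^(−µ_czt·c_k))` using oblique
chord lengths through the five 1-mm DOI layers (so the summed efficiency
at normal incidence is 1 − e^(−0.354·5) ≈ 83%), and `T_object` an
optional uniform-water attenuation over the chord to the FOV-sphere edge
(off by default: sensitivity figures account for collimator passage and
CZT efficiency only, and they *include* penetration ("noise") photons,
which are genuine entries of the SRM). The per-ray solid-angle weight is
a modelling choice the design literature leaves unstated; optional pixel
subdivision (`pixel_subsample`) exists for convergence checks and moves
the central sensitivity by ~1.5% at the first doubling and <1% after.
Entries below `entry_floor` (10⁻¹²) are dropped; the tungsten
transmission floor defaults to 10⁻⁶ for SRM assembly and 10⁻¹² for
aperture-SNR classification.

Sensitivity is the column sum (reported in %). The aperture SNR traces
every (stride-subsampled FOV voxel) → (pixel) ray through a single MCE
and reports (number of unattenuated rays) / (Σ e^(−µ_w·x) over partially
transmitted rays), unweighted as the defining ratio reads, with a
solid-angle-weighted variant available. A reproducibility caveat: under
this solid model the computed SNR values are far below the values
reported for the original design study, and an analytic penumbra
integral shows those SNR figures and the reported sensitivities cannot
both be produced by any single knife-edge or land geometry (sensitivity
of this magnitude requires knife-edge penetration; SNR of that
magnitude requires ~1-mm lands that suppress exactly that penetration);
the implementation reports the faithful computation rather than tuning
toward either figure.

The SRM is stored as SciPy CSR and persisted to HDF5 with explicit
index-ordering metadata (rows: MCE, pixel i, pixel j, DOI layer,
C-order; columns: voxel C-order). Builds that would exceed a configurable
ray cap refuse with guidance rather than thrash.

## Phantoms

All phantoms live on the standard 96³ × 2-mm grid (other grids are
accepted) and are deterministic. The Defrise phantom alternates 6-mm
disks and gaps (slab boundaries at z = 0, 14 nonempty disks) inside a
16-cm sphere. The hot-rod phantom packs four quadrant groups of
4/6/8/10-mm rods at twice-diameter pitch in a 160 × 80-mm cylinder; the
rod:background concentration ratio (20:1 or 5:1) is authoritative and
the stated totals (1 + 0.5 or 1 + 2 mCi, 30-min acquisition) only set
the global scale. Rod counts per sector are whatever fits with a
one-diameter clear margin — no counts are published. The ictal-brain
phantom is a parametric stand-in, not an atlas: a two-hemisphere head
ellipsoid with white matter at 0.056 µCi/mL, 16 bilateral VOI pairs as
spheres at plausible stereotactic positions with table-driven
concentrations and asymmetries (the left temporal pole pinned at
0.07 µCi/mL), an 8-mm reference sphere in the right cerebellum, optional
5/6/7/8-mm lesions at 3/2.5/2/1.5 : 1 contrast to white matter, and a
2×10⁹ total-photon normalization. Metrics computed on it exercise the
exact published formulas; its geometry is configurable so a labelled
atlas can be substituted.

## Simulation and reconstruction

Forward projection is `ȳ = A·x_photons` with activity converted to
emitted photons either by the total-photon normalization or by
concentration × voxel volume × 37 kBq/µCi × time × photon yield (0.885
photons/decay for the 140.5-keV Tc-99m line — the conversion factor is
not published; this is the nuclide's branching ratio). Poisson noise is
drawn per bin from a seeded generator. The systematic-error term of the
linear model is fixed at zero.

OSEM uses the standard multiplicative update per subset with 0/0 → 0,
zero-sensitivity voxels frozen at zero, uniform initialization inside
the support, fixed ascending subset order for determinism, and subsets
formed round-robin over azimuth-sorted MCEs within rings (8 subsets of
63/62 for the full helmet). The five DOI layers are independent rows;
nothing is collapsed at full scale. Stopping rules: iteration of the
NRMSE minimum for noisy data; first iteration with |ΔNRMSE| < 10⁻⁴ (0.1
per-mille, configurable) for noiseless data. The optional post-filter is
a separable Gaussian of 6-mm FWHM, renormalized to preserve the image
sum to 10⁻⁶ relative.

## Fisher information and metrics

For the Poisson model the FIM is `J = Aᵀ diag(1/ȳ) A` with ȳ the mean
projection of a uniform-FOV object; single columns are computed on
demand (never the full product) and rearranged on the grid as FIM
images. Profile FWHMs interpolate the half-maximum crossings linearly
and walk from the profile maximum, tolerating the one-voxel peak shifts
that coarse grids produce. An isotropy report probes 18 configurable
off-centre positions (±2.5/5/7.5 cm per axis) and tabulates the FWHM in
all three directions, degrading to NaN where a position has no usable
peak. Metrics (NRMSE, CRC, CNR, NC, CRC–NC curves,
uptake ratio, asymmetry index, best-CNR iteration) use ROI means over
voxels whose centres fall in the mask, without partial-volume weighting;
hot-rod reporting follows the convention of averaging the four central
slices.

## Desk-scale study protocol

Full-scale SRMs (96³ voxels × 502 MCEs × 80²×5 bins) are not desk-scale,
so the imaging studies in the test suite run a reduced protocol chosen
once: 12 MCEs spread evenly over the helmet, cropped 18×18-pixel modules
of 0.5-mm pitch (9-mm module) and a single collapsed 5-mm DOI layer,
with grids of 2–3-mm voxels restricted to the centrally visible region.
Cropping the module rather than coarsening the pitch keeps the
detector-blur contribution common to all apertures, so aperture
*orderings* and *ratios* transfer even though absolute resolutions are
degraded; single-voxel sensitivities and aperture SNRs, which touch one
voxel or one module, run at the full 502-MCE geometry. What passing at
this scale does **not** show: claims that hinge on full angular sampling
(e.g. the combined 3-type collimator's failure to resolve the Defrise
disks, which requires the full-scale view sparsity per lofthole type and
thousand-iteration convergence) do not manifest at 12 MCEs, and
4-mm-rod resolvability is sub-Nyquist on 3-mm voxels, so the hot-rod
study asserts the contrast trends instead.

## Known limitations

Scattered photons, detector charge sharing/trapping, readout
electronics, energy-window effects and dead time are not modelled. The
aperture solid shapes are reconstructed from printed parameters and
their stated purposes; where the source material is internally
inconsistent (ring radii, SNR magnitudes) the choice and its evidence
are documented above rather than hidden. The brain phantom is
geometric, not anatomical. Ray marching is discretization-controlled,
not analytic CSG; its step is configurable and oracle-bounded in tests.
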