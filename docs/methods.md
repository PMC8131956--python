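# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generator does and does not
emulate, and the known limitations.

## Coordinate model

Structures are ordered heavy-atom records in Å. All chains are mapped onto
one continuous 1-based numbering: the first chain keeps its author
numbering and each later chain continues where the previous one ended, so
a Fab light chain occupies 1–214 and the heavy chain 215–442. Hydrogens
are dropped on read (`keep_h=True` retains them); every metric is
heavy-atom, and "all-atom" RMSD means all heavy atoms including side
chains. Insertion codes are rejected; for alternate locations the first
record is kept. The default domain map (VL 1–108, CL 109–214, VH 215–334,
CH1 335–429; interfaces VL–VH and CL–CH1) excludes the hinge 430–442 from
every domain-level metric while whole-protein metrics retain it. The
default 34-strand map fixes the handful of strand intervals with published
anchors and fills the rest with a regular nominal layout — it is a
config-replaceable placeholder, not a crystallographic assignment.

## Superposition metrics

The Kabsch fit is the standard SVD solution with the determinant sign
correction, optionally mass-weighted. Domain RMSD superposes each frame on
the reference using only the domain's atoms, so rigid inter-domain motion
never inflates intra-domain deformation. Windowed RMSF partitions frames
into consecutive non-overlapping windows by time (default 10 ns; a frame
landing exactly on a boundary joins the preceding window, so 0–100 ns at
0.1 ns/frame gives exactly ten windows). Within a window, each frame is
fitted to the *static reference* on the region's atoms in a single pass
and fluctuations are taken about the window-mean coordinates — not
iteratively re-fitted to the evolving mean; the convention is fixed and
deterministic. Per-residue RMSF is the mean over the residue's atoms.
Replicate aggregation reports mean and SEM = sd/√n with the n−1
denominator; a single replicate reports SEM 0 and is flagged. Masses come
from a fixed element table; unknown elements get the carbon mass with a
warning.

## Native contacts

A native contact is a heavy-atom pair within 4.5 Å in the reference
structure; intra-domain sets exclude pairs closer than 3 residues in
sequence (trivially bonded neighbours), interface sets keep all
cross-domain pairs because sequence separation is meaningless across
chains. The retained fraction is the logistic soft-cutoff score with
β = 5 Å⁻¹ and λ = 1.8 — the standard soft-cutoff constants for heavy-atom
contact analysis. All four constants are config-exposed (`ContactParams`),
never hard-coded downstream, so a different published parameterization can
be dropped in. The logistic argument is clipped at ±500 to avoid overflow;
residue-level Q is the mean score over all pairs involving the residue
(residues without native pairs are absent from the map, not zero). Total
contacts count cross-set pairs within 6.0 Å, the conventional default of
the minimum-distance tools used for this purpose.

## Salt bridges

Detection is residue-level with the any-atom rule: an (acidic, basic) pair
is formed in a frame if any carboxylate O (Asp OD1/OD2, Glu OE1/OE2) is
within 3.2 Å of any basic N (Lys NZ, Arg NE/NH1/NH2). Histidine is
excluded by default because its participation is protonation-dependent;
`include_his=True` adds ND1/NE2. Occurrence is the percentage of frames
formed; pairs never formed are absent (sparse), and replicate aggregation
fills missing entries with 0 before computing mean ± SEM. The 10 %
reporting threshold is applied to the replicate *mean* (configurable), an
explicit choice where per-replicate thresholding would also be defensible.
A residue may appear in several rows with different partners; no
exclusivity is enforced. Region counting buckets a pair as intra-domain,
as a named interface when the partners occupy the paired domains, and
otherwise (including hinge residues) as "other".

## Secondary structure

Only the extended (E) state is implemented; helices, turns, bends and
isolated bridges map to "other", because the downstream analysis is
exclusively β-strand occupancy. Amide hydrogens, absent from a heavy-atom
model, are reconstructed 1.00 Å from N along the previous residue's C→O
direction; chain-initial residues and prolines carry no H, and a peptide
C–N distance above 2.5 Å is treated as a chain break. The Kabsch–Sander
energy uses the 27.888 kcal·Å/mol coupling and the strict E < −0.5
kcal/mol bond criterion; distances under 0.5 Å flag a clash and return the
conventional −9.9. A CA–CA < 9 Å prefilter bounds the pair search; it
cannot change results because the energy at 9 Å is far above the cutoff.
Bridges follow the parallel/antiparallel bond patterns and only ladders of
≥ 2 consecutive bridges yield E. Per-strand occupancy change between
conditions is *relative* percent change by default
(100 × (occ_stress − occ_ref)/occ_ref per replicate pairing, mean ± SEM);
absolute percentage-point difference is available via `relative=False`
and the output labels which mode was used. A strand never β in the
reference yields a missing value with a warning, never ±∞.

## Surface and packing

SASA is Shrake–Rupley with golden-spiral dots (default 960/atom), probe
1.4 Å, and the radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å; unknown elements
get the carbon radius with a warning, hydrogens never contribute. The dot
error against the analytic isolated sphere is well under 2 % at the
default dot count. The APR exposure table averages each APR's summed SASA
over frames (full trajectory by default, a stride is configurable) and
reports 100 × (mean_stress − mean_ref)/mean_ref per replicate pairing.

OSP casts the outward normal ray from each dot on the *bare van der Waals
sphere*; a ray entering a neighbouring vdW sphere within RL_max = 2.8 Å
(one water diameter) contributes weight 1 − RL/RL_max. Atom OSP is the
mean dot weight; residue OSP is the vdW-area-weighted mean. Starting rays
on the vdW sphere rather than a molecular surface is a deliberate
simplification that keeps the score bounded in [0, 1] and monotone under
added neighbours — absolute OSP values are therefore comparable within
this tool only, and reproducing any particular published OSP average is
out of scope.

## Sequence statistics

The mutation universe of a length-L sequence is exactly 19 L substitutions
(8398 for 442 residues). ΔΔG tables must declare the sign convention
(`# ddg_convention: negative=stabilizing`) in their first line and are
rejected otherwise; "stabilizing" is the strict inequality ΔΔG < threshold
(default 0), so a mutation scoring exactly zero is not stabilizing.
Alignment entropy is Shannon entropy in natural log over the 21-symbol
alphabet (20 amino acids + gap) — the nats convention is forced by the
3.04 = ln 21 maximum; gap-only columns are single-symbol columns with
H = 0, not errors. APR consensus selects residues called by at least 3 of
the supplied predictor masks and emits maximal runs as intervals.

## Synthetic data generator

The mini-Fab is four 24-residue β-sandwich domains (two stacked
two-stranded antiparallel sheets of ideal backbone geometry, φ = −139°,
ψ = +135°, ω = 180°, standard bond lengths) on continuous numbering 1–96:
light chain VL + CL, heavy chain VH + CH1, arranged so VL–VH and CL–CH1
form inter-chain interfaces with tens of native contacts each. The partner
strand of each sheet is the mirrored strand placed by a frozen transform
(separation, register shift and two small tilts) obtained once from a
deterministic optimization of the total Kabsch–Sander H-bond energy; the
resulting bonds sit at −2 to −3 kcal/mol, far below the −0.5 cutoff, so
strand assignments are robust to the default jitter. Every residue carries
an inward pseudo-CB that packs the sandwich core. Designed salt-bridge
residues (two Glu- and two Asp-containing pairs by default) carry pseudo
side-chain O/N atoms arcing over a free face at the designed 2.8 Å O–N
distance; designed APR segments are interior strand residues shielded by
the opposing sheet.

The three condition profiles are the study defaults: `reference`
(σ = 0.15 Å i.i.d. Gaussian jitter, bridges held at 60–90 % occupancy),
`low_ph_like` (same jitter; a 0→2 Å ramped, centroid-balanced pair
displacement localized in CL; Glu bridges eliminated; the CL APR exposed
in 40 % of frames) and `high_temp_like` (σ = 0.45 Å; a 0→6 Å rigid
separation of the heavy-chain block stressing both interfaces; all bridge
occupancies reduced; the VH APR exposed in 50 % of frames). Trajectories
default to 101 frames at 1.0 ns — a 100-ns-equivalent span at desk-scale
cadence. Replicate seeds derive from the master seed via
`SeedSequence(master).spawn`, so replicate sets are independently
reproducible.

Three design choices make ground truth exact rather than statistical:
scheduled atoms (bridge pseudo-atoms, designed APR segments) are exempt
from jitter; bridge and exposure schedules are deterministic frame masks
(formed in the first ⌊f·n⌉ frames, exposed in the last ⌊f·n⌉); and the CL
deformation displaces residue pairs in opposite directions along their
centroid axis, which keeps the optimal superposition at the identity and
gives the fitted RMSD the closed form α·√(n_displaced/n_region). The
emitted ground truth records exact occupancies, the closed-form
deformation RMSD (valid when bridge schedules are held), the noiseless
final-frame interface Q, and a two-state APR prediction: condition-mean
SASA = (1−f)·S_buried + f·S_exposed with both areas measured once on the
static states. Measured %-SASA changes are inverted through this relation
(`recover_exposure_fraction`) to compare recovered against designed
exposure fractions; under the high-jitter condition the direct %-change
carries a few points of jitter-induced baseline bias while the recovered
fraction stays within ±5 percentage points of the design.

What the generator does *not* emulate: correlated physical motion (jitter
is i.i.d. per atom), solvent, force-field energetics, realistic side
chains, or genuine burial — with backbone-plus-pseudo-CB sandwiches the
APR segments are strongly shielded but not near-zero SASA. Passing tests
therefore demonstrate the correctness of the metric implementations and
the recoverability of designed signals at realistic noise amplitudes, not
the physics of any real protein.

## Pipeline

`run_comparison` validates the config and the existence of every input
file before computing anything, then writes per-condition CSVs and, for
each stress condition, the versus-reference tables and per-residue
Δ(RMSF)/Δ(Q) maps projected onto the structure's B-factor column
(clamped to the printable −9.99…999.99 range). The Δ convention is
everywhere stress − reference as two signed columns. Replicates are
paired by index when counts match; otherwise the pipeline warns and falls
back to unpaired means with SEMs combined in quadrature. Floats are
written with 6 significant digits, so re-runs on identical inputs are
byte-identical. A manifest JSON records the package version, seed and all
parameters.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 96-residue
mini-Fab (~500 atoms) with 11–51 frames and 1–6 replicates, and the
recovery properties over 20 seeds — sizes chosen so the whole suite
exercises every stage in about a minute of CPU. A `fab-scale` run (442
residues) uses the same code paths unchanged; only the fixture sizes
differ.
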