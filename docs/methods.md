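# Methods

This note documents the models, parameter conventions, synthetic-data
design and numerical choices behind the `coreceptor` package. Units
throughout: residue indices 1-based inclusive, distances in Å, masses in
Da, concentrations in nM, energies in kcal/mol, times in ps.

## Sequence segmentation (`seqann`)

A canonical AUX/IAA is segmented by three sequence landmarks:

1. the core degron, the first match of `VGWPP[VI][RG]..R` (10 residues);
2. the first KR dipeptide strictly upstream of the degron, which closes
   domain DI (DI = residue 1 through the R of that dipeptide);
3. the first VKV motif at or after the degron end, which opens the PB1
   domain (PB1 = VKV start through the C-terminus).

The linker is whatever lies between KR and the degron, the degron tail
whatever lies between degron end and PB1 start; when the protein is
canonical the five spans tile the sequence exactly, and
`degron_tail_length = PB1.start − degron.end − 1`. First-match tie-breaking
applies to both the degron and VKV; extra degron matches emit a warning.
Sequences without a degron or without a downstream VKV get a partial,
non-canonical annotation. A protein with no KR upstream of the degron has
an empty DI and a linker starting at residue 1.

The family literature describes the degron as 13 residues; the
machine-checkable regex spans 10. The stored span is the regex match;
`extended_degron_span(ann, left_ext=3)` restores the 13-residue display
convention, with the extension exposed because boundary conventions differ
between published figures (tail lengths quoted as 36/49 aa in one place
and <30/44 aa in another are a boundary-convention difference we do not
reconcile).

Disorder classification uses the standard IUPred-score thresholds:
disordered > 0.6, ordered < 0.4, intermediate in the closed interval
[0.4, 0.6]. The three fractions always sum to 1; a sub-span argument
supports excluding the folded PB1 domain. Hydropathy is the Kyte–Doolittle
sliding-window mean with a default window of 9 (the common web-tool
default; the window shrinks symmetrically at the termini so the profile
has exactly sequence length).

Construct numbering offsets (e.g. 5 or 2 extra N-terminal residues on
expression constructs) live on `ProteinRecord.offset` and are applied only
when exchanging residue indices with external crosslink tables — they
never shift the segmentation itself.

## Hydrodynamics (`hydro`)

SEC calibration regresses log₁₀(R_S) on elution volume (the familiar
log-linear gel-filtration linearization) over ≥ 3 standards; the fitted
line inverts to give R_S for sample elution volumes. Degenerate identical
volumes are rejected.

Theoretical Stokes radii follow Uversky-type power laws
log₁₀(R_S) = a + b·log₁₀(M) per conformational class (natively folded,
molten globule, premolten globule, disordered). The paper trail for the
exact coefficients runs through method papers rather than the analysis
itself, so the coefficients ship as a citable data file
(`data/stokes_laws.json`) with three IDP variants: the natively-unfolded
coil calibration (default) and the urea-/GdmCl-unfolded alternatives.
A hand-evaluation test pins the default set at 25 kDa. For every shipped
set the band ordering NF < MG < PMG < IDP holds over 5–100 kDa and all
exponents lie in 0.3–0.6.

Classification assigns the class whose ±10% band contains the measured
radius. With the shipped coefficients the NF and MG bands overlap across
the whole protein mass range; a measurement inside several bands goes to
the nearest band center, and a measurement inside none is reported as the
nearest class flagged `outside_band`. The round trip
`classify_fold(theoretical_rs(m, c), m) = c` holds exactly for all classes
and masses because the true center is always the nearest.

## Saturation binding (`binding`)

Model: B_total(x) = B_max·x/(K_d + x) + NS·x, with free ligand
approximated by added ligand (no depletion correction — consistent with
receptor concentrations far below K_d in the assay design). Fits run on
raw counts; curve normalization (`normalize_relative`) is
presentation-only because normalizing destroys the B_max scale.

Two fitting modes: `joint` co-fits (K_d, B_max, NS); `pinned-ns` first
fixes NS by a through-origin linear fit to the cold-competition controls
and then fits (K_d, B_max). Initialization is deterministic: NS₀ from the
incremental slope of the two largest concentrations, B_max₀ from the
maximal baseline-corrected signal, K_d₀ from the concentration nearest
half of it. The K_d standard error comes from the Jacobian covariance;
non-convergence is reported through `converged=False` with the last
iterate, never an exception. When the design cannot identify K_d (maximum
concentration far below it) the joint mode can trade B_max against NS;
the pinned-ns mode then reports the identifiability loss honestly through
a K_d standard error exceeding the estimate itself.

Default simulation design: 10 log-spaced concentrations 1–2000 nM in
technical triplicate with 10% multiplicative log-normal noise (unit-mean),
mirroring the assay layout; B_max = 1 and NS = 5·10⁻⁴ per nM set the
nonspecific contribution to a realistic share of the top-concentration
signal. Under these conditions the median refit K_d over 200 seeds lands
within a few percent of truth at all four studied affinities (20, 53,
143, 200 nM), and ±2·SE intervals cover the truth in ≥ 80% of fits.

## Crosslink restraints (`xlink`)

Crosslink identity is the unordered endpoint pair after offset correction;
replicate support is the set of replicates the pair appears in. The
reproducibility filter keeps pairs with support ≥ `min_support` (the 2-of-3
/ 3-of-4 convention) and labels unanimous support `solid`, the rest
`dashed`. The filter is idempotent and monotone in `min_support`.
Single-linkage 1D clustering with a default `max_gap` of 30 residues
summarizes crosslinker-reactive receptor residues into spans.

Each resolvable inter-protein link becomes a Cα–Cα restraint with default
bounds [0, 30] Å — the DSBU spacer (~12.5 Å) plus side-chain and backbone
allowances; the exact value is configurable and logged into the restraint
file header. Endpoints without coordinates (IDR residues outside any
model) are listed as unresolvable rather than fatal. The degron-tail
restraint converts tail length n to a peptide mass n·110 Da and bounds the
anchor separation by scale·R_S(NF) and scale·R_S(IDP) with a geometry
factor of 2 (end-to-end distance ≈ 2·R_S); mean residue mass and scale are
parameters since no single convention exists. Restraints export in the
ambiguous-`assign` dialect (d = upper, dminus = upper − lower, dplus = 0)
with byte-stable sorted ordering, and parse back losslessly.

## Accessible interaction space (`ispace`)

A deliberately coarse re-implementation of restraint-driven
interaction-space counting: ligand centers enumerate a cubic grid over the
receptor bounding box (padding defaults to ligand extent + largest
restraint upper bound), combined with a deterministic super-Fibonacci
rotation set (spiral irrationals √2 and the real root of x⁴ = x + 4).
Defaults: 2 Å grid, 576 rotations, 3 Å clash distance. A placement is
accessible iff the minimum inter-body bead distance is at least the clash
distance; `counts[k]` totals accessible placements satisfying ≥ k
restraints, so `counts[k]` is non-increasing and `counts[0]` is the
clash-only census.

Correctness is anchored to an independent brute-force oracle (naive
triple loop over the identical placement set) on fixtures of ≤ 10⁴
placements — not to any FFT-accelerated reference, because the claim being
reproduced is the shape of the counts-vs-restraints curve, not absolute
counts from a particular tool's sampling. Bodies are expressed in a
canonical frame (centroid + sign-fixed principal axes) before gridding, so
counts are invariant under rigid motion of the whole system whenever the
covariance spectrum is non-degenerate; symmetric bodies fall back to lab
axes. The restraint-application curve applies restraints cumulatively
(crosslinks first, tail last); on the two-lobe fixture the tail restraint
removes an entire placement lobe, producing the characteristic sharp final
drop. Interaction propensity normalizes per-residue contact frequency
(contact distance default 5 Å) by the mean over contacted residues, so the
contacted-residue mean is 1 by construction and the active set is the
strict excess (> 1.0).

## Energy post-processing (`energetics`)

Consumes per-frame ΔG_eff tables and per-residue decompositions; the
MM-GBSA evaluation itself is upstream. `sample_count` checks the
duration/interval arithmetic (20,000 ps / 10 ps → 2000 frames).
Accumulated means are running means; equilibration statistics use the
inclusive window time ≥ t_eq with SEM treating frames as independent by
default — a block-averaging SEM (10 blocks) is available because MD frames
are autocorrelated and the independent-frame SEM understates uncertainty.
Group selection takes the lowest equilibrated mean, with deterministic
group-id tie-breaking under a warning. Hot-spots are residues with
side-chain contribution ≤ −1.0 kcal/mol (boundary inclusive), sorted
ascending; the call is monotone in the threshold. Alanine-scan ΔΔG is
mean(mut) − mean(wt) over post-equilibration windows with SEM propagated
in quadrature; the frame subsampling behind the SEM is a parameter because
published conventions vary.

## Synthetic-data design (`synthdata`)

Generators draw from a single explicitly seeded `numpy` Generator each and
are byte-deterministic under a fixed seed; every generator returns a
machine-readable truth record.

- **Sequences**: module lengths drawn per record (DI 10–40, linker 4–30,
  tail 0–60, PB1 60–100 aa); the alphabet upstream of the degron excludes
  Arg and Val so neither a spurious KR nor a degron can appear, and the
  tail alphabet excludes Val so no early VKV can pre-empt the PB1 start.
  Planted spans are therefore recovered exactly — these tests verify
  bookkeeping, not robustness to motif ambiguity in real proteomes.
- **Binding**: counts are model values × unit-mean log-normal noise at a
  given CV (default 10%).
- **Crosslinks**: true links join receptor residues drawn from two windows
  (defaults 140–229 and 485–529, emulating the two crosslink-reactive
  clusters) to ligand residues outside a nominal degron; each true link
  appears in ≥ min_support replicates, decoys in exactly one. Filter
  recovery is exact by construction.
- **Toy structures**: three fixed geometries (brute-force-verifiable
  census; two-lobe wall geometry where only the tail restraint removes a
  lobe; mirror-symmetric propensity control), each ≤ 20 beads with its
  census precomputed by the naive oracle.
- **Energies**: ΔG_eff = plateau + transient·exp(−t/τ) + Gaussian noise
  (defaults −45 + 15·exp(−t/1500 ps) ± 2 kcal/mol over 20 ns / 10 ps);
  decomposition tables plant hot-spots strictly below −1.0 and background
  strictly above; CAS pairs plant a known ΔΔG.

What the generators deliberately do not emulate: spectral-level crosslink
false identification (tables arrive post-FDR), autocorrelated MD noise
(frames are drawn independent, which is why the block SEM exists),
ligand depletion in binding assays, and real IDR compositional bias.
Passing the recovery tests therefore demonstrates the algorithms are
implemented correctly under their stated assumptions, not that those
assumptions hold for any particular experimental data set.

## Problem sizes and external-scale quantities

Toy interaction-space fixtures are sized to a few thousand placements so
the brute-force oracle can certify them exactly; the simulate-and-refit
studies use 200 seeded datasets per affinity. Absolute
accessible-complex bar heights, absolute MD energy magnitudes and the
empirical receptor cluster spans depend on deposited experimental data and
full DisVis/AMBER runs; they are outside what synthetic fixtures can
certify and are covered instead by the corresponding algorithmic
properties (oracle equality, curve monotonicity and the tail-drop shape,
cluster recovery of planted windows).

## Known limitations

- Rigid-motion invariance of the scan relies on a non-degenerate principal
  frame; perfectly symmetric receptors are gridded in lab axes.
- The scan is O(grid × rotations × beads) with no FFT acceleration: it is
  a verification instrument, not a production docking tool.
- Fold-class bands overlap at protein masses (NF/MG especially); the
  nearest-center rule resolves membership, but a single SEC measurement
  cannot sharply distinguish adjacent classes there.
- The one-site fit assumes free ≈ added ligand; strong depletion would
  bias K_d low.
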