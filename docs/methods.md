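# Methods

`fishratio` re-implements an automated dual-probe HER2 FISH quantification
workflow: fluorescent spot counting in a Spectrum Orange (HER2) and a
Spectrum Green (CEP17) channel over a DAPI counterstain, sampled either by
non-overlapping square tiles or by segmented nuclei, with the pooled
HER2/CEP17 ratio mapped onto the clinical amplification categories.  This
note records the model, the parameters that matter, what the synthetic
material does and does not emulate, and the design choices made where the
procedure was genuinely open.

## Scoring model

A specimen is scored from 5–10 microscope fields (1088 × 880 px, 8-bit per
channel).  Per accepted sampling unit (tile or nucleus) the spot-equivalent
counts of both probes are summed; the case ratio is Σ HER2 / Σ CEP17, which
equals the quotient of the per-unit averages because the unit count cancels,
and avoids dividing by zero in sparse units.  Categories: ratio < 1.8
nonamplified, 1.8 ≤ ratio ≤ 2.2 equivocal (closed band on both ends, so a
ratio of exactly 2.2 is equivocal), ratio > 2.2 amplified.  Equivocal cases
with ratio ≥ 2.0 carry an eligibility flag because such patients remain
candidates for targeted therapy.

## Spot detection

Each probe channel is processed by Gaussian smoothing (σ = 0.1 μm), a white
top-hat with a disc element (radius 0.5 μm; passes single probe signals of
~0.2–0.5 μm, removes nuclear-scale background), and a negated
Laplacian-of-Gaussian clipped at zero.  A spot is a connected component of
the processed image above `intensity_frac` of the channel's reference
maximum, with thresholded area ≥ `min_area_um2`; components whose centroids
lie closer than `min_distance_um` are merged by single linkage (merging
preserves total signal and matches how a human counts an unresolved
doublet).  Channel defaults: HER2 0.05 μm² / 0.8 μm / 33%; CEP17 0.18 μm² /
0.5 μm / 30%.

Two interpretation choices the published parameters leave open:

* **Relative intensity.**  The percentage thresholds are taken relative to
  a robust channel maximum — the 99.9th-percentile processed intensity
  *inside the counterstain mask*.  Restricting to nuclear pixels matters:
  probe signal occupies a roughly constant fraction of nuclear area, while
  against a whole-field percentile a sparsely populated field drops the
  reference into the background noise and floods the detector with specks.
* **Mask gating.**  Candidate objects whose centroids fall outside the
  counterstain mask are discarded; signals outside nuclei are artifacts.

## HSR area mode

In specimens amplified through homogeneously staining regions (HSR), HER2
signals form clusters whose members cannot be resolved.  The spot-scale
filter chain deliberately suppresses structure wider than a single signal,
so a cluster fragments into a few small objects that under-represent it.
Area-mode counting therefore measures *signal area* on the
Gaussian-smoothed channel only: spots whose centroids share a connected
smoothed-signal component **larger than `hsr_factor` (default 4) times the
typical single-signal area** (median over single-occupancy components) are
unified into one object carrying the component's area; smaller shared
components are resolvable neighbours and keep their identities, splitting
the area proportionally.  Objects whose area exceeds `hsr_factor` times the
case's reference single-spot area (median isolated-spot area; fallback
0.15 μm² when fewer than five isolated spots exist) are converted to
`round(area / reference)` spot-equivalents (minimum 2) and the case is
flagged `hsr_mode_used`.  On synthetic 12-copy clusters this recovers
~13 equivalents — the merged object includes the halo between members, so
area-mode equivalents mildly overstate copy number; classification is
unaffected since such cases sit far above the 2.2 boundary.

## Tile sampling

Axis-aligned 71-px squares are placed greedily by descending counterstain
coverage over a candidate lattice (8-px stride plus the exact 71-px tiling
lattice), ties broken row-major, overlaps forbidden; if the exact tiling
lattice alone would cover more mask pixels than the greedy set, it is used
instead, so the placement never covers less than the plain grid.  Tiles
with coverage < 40% (boundary inclusive: 40% is accepted) or fewer than two
fluorescent signals in total are rejected; zero-signal tiles are rejected
on the same rule because they cannot inform a ratio.  A case with fewer
than 32 accepted tiles, pooled over its fields, is rejected.  Spots are
assigned to tiles by half-open pixel boxes so no signal is double-counted
on shared borders.

## Nuclei sampling

The counterstain mask (Otsu threshold, holes filled, objects < 2 μm²
removed) is split into nuclei: connected components are divided by a
distance-transform watershed when solidity < 0.9 or area > 1.5× the
expected single-nucleus area (median component area by default), with seeds
at distance-map maxima ≥ 2 μm apart.  A nucleus is accepted when its area
lies in [12, 400] μm², its circularity 4πA/P² is ≥ 0.60, it does not touch
the image border, and it carries at least one signal of each probe (the
signal-quality rule borrowed from manual-scoring eligibility).  All other
regions stay *pre-segmented*.  A case needs ≥ 20 accepted nuclei, mirroring
the minimum enumeration convention of manual scoring; the automated
procedure's own minimum is not published, so this default is an assumption.

Five human-correction operations are supported headlessly — add (polygon),
select, delete, split (polyline), merge — validated before any mutation,
journaled for replay, and each followed by an automatic result update.
User-added nuclei bypass the gates: the interactive phase exists precisely
to override the automatic selection.

## Synthetic material

The generator plants textured elliptical nuclei (equivalent diameter
9 ± 1 μm — typical for breast-carcinoma tumour nuclei — clamped below at
0.7× the mean, axis ratio 0.7–1.0) in 1088 × 880 px fields at 0.16 μm/px,
with per-nucleus probe counts drawn as **1 + Poisson(λ − 1)**: mean exactly
λ, support ≥ 1.  Plain Poisson would produce zero-count nuclei that the
≥1-of-each gate excludes, biasing the accepted-population ratio away from
the planted one by ~15% at λ = 2; and every real nucleus carries at least
one chromosome-17 centromere, so truncation is also the realistic choice.
Signals are Gaussian blobs (σ 0.22 μm HER2, 0.30 μm CEP17 — centromeric
signals are visibly larger; amplitudes 200–240), optical blur σ 0.1 μm,
additive background noise (sd 2), 8-bit quantisation applied last so the
noise statistics are honest.

**Separation guarantee.**  Planted signals of one channel keep a pairwise
distance of at least the maximum of 1.2× the channel merge distance, 3.5×
the total signal width (rendered ⊕ smoothing ⊕ LoG; two equal Gaussian
profiles bridge above the relative threshold up to that distance), and
4.3× the smoothed-only width (relevant to signal-area consolidation, which
lacks the LoG's saddle-carving).  This makes planted count = detectable
count: every recovery experiment compares the detected ratio with the
*realized* planted ratio (Σ/Σ of the counts actually planted), the only
well-defined target once counts are random.  A nucleus whose drawn count
exceeds its packing capacity at this separation is clamped to capacity
(~55% of close packing, the jamming density of random sequential
placement); the ground truth records the planted counts.

HSR clusters are rendered as a phyllotaxis (sunflower) layout of the
specified copy number at 0.35-μm radial scale: nearest-neighbour spacing
stays below the HER2 merge distance, so members are genuinely unresolvable
and collapse into one detected object whose smoothed area carries the copy
number.

Cohort presets: nonamplified λ_H = λ_C = 2; amplified λ_C = 2 with 12-copy
clusters in 80% of nuclei (non-HSR nuclei at λ_H = 8); amplified_no_hsr
λ_H = 8, λ_C = 2; equivocal λ_H = 4, λ_C = 2 with cases redrawn until the
realized ratio lies in [1.8, 2.2], so planted labels hold by construction.
Realism knobs for the known failure modes of automated scoring exist but
default off: `blurred_dapi` (poor-quality counterstain) and direct λ_C
overrides for aneuploid (monosomic/polysomic) populations.

What the generator does **not** emulate: stromal and autofluorescent
texture, sectioning artifacts (truncated nuclei away from borders), probe
cross-talk, and focal blur gradients.  Passing tests therefore demonstrate
correctness of the counting and sampling machinery under controlled
imaging physics, not clinical performance on tissue.

## Problem sizes in the validation experiments

Validation cases use one 1088 × 880 field of 60 nuclei per case (tile-mode
experiments: two fields of 100–120 nuclei), chosen so each experiment
exercises the full pipeline at the published field geometry while a cohort
of 32 cases remains a desk-scale computation.  Headline published
concordances were measured on 64/28/29 real specimens that are not
deposited; the synthetic cohort experiment mirrors the design (32 clearly
nonamplified cases, 100% automated concordance) rather than re-measuring
those numbers.

## Numerical conventions

Pixel coordinates are 0-based row-major; boxes and regions use half-open
conventions; physical parameters are stored in μm and converted through
`um_per_px` at use time (default 0.16 μm/px, making a 71-px tile ≈ 11.4 μm
— one or two nuclei — since the capture station's true calibration is not
part of the published parameters).  Merge/threshold comparisons are strict
(`<` merge distance, `≥` area and intensity gates) with 1e-9–1e-12 epsilon
guards against float round-off.  Degenerate inputs: constant images yield
empty masks and no spots; an all-background field scores as a rejected
case; a zero CEP17 total in a non-rejected case raises an undefined-ratio
error rather than silently producing infinity.

## Known limitations

* Area-mode spot-equivalents overstate tight-cluster copy number by the
  inter-member halo (~10% on the synthetic 12-copy clusters).
* The watershed splitter needs a usable expected-nucleus-area estimate; in
  fields with very few components the median estimate degrades (callers
  can pass `expected_area_um2` explicitly).
* The greedy tile search is a deterministic heuristic with a lattice lower
  bound, not an exact maximizer of covered nuclear material.
* The mixed-cell-population ratio estimation used by some commercial
  systems for heterogeneous specimens is out of scope.
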