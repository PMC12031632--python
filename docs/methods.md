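# Methods

This note documents the model behind `circledet`, the choices made where
the design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Model and assumptions

The detector assumes circles manifest as closed or partially occluded
intensity boundaries in a single-channel image. It is built around two
perceptual constants from which every other threshold derives:

- **λ = 0.05** — the minimum length-difference discrimination ratio. Two
  arc lengths differing by less than 5 % are treated as perceptually
  identical. This motivates the radius-adaptive fit tolerance
  TDS = clamp(r·λ, [TDP, K]): the permissible radial deviation of a
  segment from a circle grows with the radius, between the fixed
  point-inlier tolerance TDP = 1 px and the ceiling K.
- **K = 3 px** — the minimum distinguishable distance. RANSAC support
  points closer than K are rejected as geometrically uninformative;
  point-set suppression discards structures contributing at most K novel
  points; the tolerance clamp tops out at K.

Derived constants are stored, not re-derived: patch size L = 32, stride
S = 16, minimum structure size m_min = 16, RANSAC confidence p_f = 0.99,
completion floor α = 0.3, completion ceiling 0.9, digitization ratio
η = 0.9. All of them live in `DetectorParams`; a test enforces that no
other module hard-codes them.

## Stage-by-stage notes

**Edge extraction.** The contract is: one-pixel-wide connected chains,
no per-image hyperparameters, deterministic. The implementation smooths
with a 5×5 Gaussian (σ = 1), takes Sobel gradients, and delegates
non-maximum suppression plus hysteresis linking to the Canny machinery
of scikit-image — with both thresholds computed from the image: the
strong threshold is max(Otsu split of gradient magnitudes, σ̂·√(2 ln N)),
where σ̂ is the MAD-based estimate of the noise gradient spread and N
the pixel count. The second term is an a-contrario bound: in a pure-noise
image the expected number of pixels above it is below one, so edge
chains that survive cannot be accidental — the same rationale as
Helmholtz-principle validation, in a much simpler form. Chains shorter
than 8 px are discarded; two-subiteration thinning guarantees unit
width. An earlier hand-rolled sector-quantized NMS was abandoned: it
dropped a quarter of the crest pixels on curved boundaries, which
starves the completion filter downstream. The stage is pluggable — any
binary edge map can be passed in directly.

**Patch RANSAC.** The iteration count N = ⌈log(1−p_f)/log(1−(m_min/|V|)^t)⌉
is recomputed from the *current* point count at the start of every
extraction round, since accepted structures remove their inliers. Line
(t = 2) and circle (t = 3) hypotheses run their full budgets each round
and compete; the larger inlier set wins, ties going to the circle
because large-radius arcs mimic lines inside a 32-px window. Sampling is
vectorized in blocks; an N cap of 10⁵ guards the near-divergence of the
budget when |V| barely exceeds m_min. Each patch draws its own generator
seeded by (run seed, patch origin), so results are independent of patch
processing order and reproducible in parallel.

**Circle fitting.** Kåsa's algebraic least squares, solved in centered
coordinates. It is closed-form, deterministic, and exact on noise-free
data, which keeps every call site consistent; no geometric refinement
step is applied anywhere, so fitted parameters mean the same thing in
every stage. Collinear point sets raise a degenerate-fit error that
callers map to "no circle" — near-infinite-radius artifacts would poison
the parameter-space synthesis. The collinearity test is an eigenvalue
ratio of the scatter matrix (1e−9 relative), far below the curvature of
any radius the detector targets.

**Hierarchical search.** Merge passes iterate longest-first over a
snapshot of the library, committing merges immediately so later
iterations see merged segments. Whether a segment merged in the same
pass may merge again is ambiguous in a bottom-up scheme; immediate
commit was chosen (a merged segment can absorb another partner in the
same pass), which converges faster and never violates the distance
criterion since every union is re-validated. Arc extension needs an
"outward" direction: the support points' angular interval is taken as
the complement of their largest angular gap, and endpoints advance into
the gap by arc length m_min/2. Segments whose largest gap is shorter
than K along the circumference are complete circles and are not
extended. Model-less segments that find no partner are deleted — this is
what removes straight-line clutter.

**Parameter synthesis.** Nearest neighbours use unweighted Euclidean
distance over (a, b, r) in pixels; radius and position are commensurate
(both in pixels) and no scaling is specified by the design, so none is
applied. An entry whose five neighbours all fail the joint-fit criterion
is carried through unchanged rather than dropped: a literal reading of
the synthesis loop would silently discard isolated circles, which is
plainly not intended (isolated circles must be detectable). This
carry-through is the single most behaviour-affecting interpretation in
the package.

**Completion filter.** TL(r) = max(0.9 − (0.9 − α)·r·λ/K, α). The scale
factor r·λ/K sweeps the threshold from 0.9 (tiny circles must be nearly
complete) down to α at r = K/λ = 60 px. The alternative reading r·K/λ
(available as `literal_completion=True`) pins TL at α for every radius
above one pixel, making the radius dependence vacuous; it is kept only
for comparison. η = 0.9 is validated empirically: midpoint-rasterized
circles with r ∈ [20, 100] contain between 0.85·2πr and 0.95·2πr pixels.

**Matching.** Disk IoU is computed in closed form via the circular-lens
area. Matching is one-to-one and greedy by descending IoU with a strict
> 0.8 threshold; a duplicate detection of an already-matched circle
counts as a false positive. This is the strict reading — it penalizes
over-detection, consistent with counting false positives at all.

## Synthetic benchmark: what it shows and what it does not

The generator renders anti-aliased filled disks (one step-edge boundary
per circle), nested concentric disks of alternating intensity, occluding
bars covering a stated fraction of a circumference, straight-line
clutter, and low-contrast bright disks on dark backgrounds; additive
zero-mean Gaussian noise (σ on the [0, 1] scale, clipped) emulates sensor
noise. Ground truth is exact by construction. Circles are placed inside
the patch-covered field of view: image dimensions that are not
stride-aligned leave a border strip (12 rows for 400×300 at the
defaults) that no admissible patch covers, so a fixture circle leaking
into it would be unobservable by construction rather than by failure.

Default study conditions: 400×300 scenes, 3–8 circles, radii 15–60 px,
10 repetitions per noise level at σ ∈ {0, 0.3, 0.6, 1.0}. These sizes
keep the full acceptance run in the tens of seconds while leaving every
stage's behaviour visible; they are the package's own benchmark scale.

Passing these benchmarks shows the geometry pipeline — budgeted
sampling, merging, synthesis, completion filtering — recovers exactly
known circles to sub-pixel accuracy under occlusion, clutter, and
moderate noise. It does **not** show robustness to textured backgrounds,
uneven illumination, soft/defocused boundaries wider than the smoothing
kernel, elliptical distortion (explicitly out of scope), or the
long-tailed content of real photographic datasets. Under extreme noise
(σ ≥ 0.6 at the default contrast of 0.7) the a-contrario edge threshold
rises above the true boundary gradient and recall collapses to zero;
the degradation is monotone and produces no false positives, but a
front end specifically hardened against such noise would fail later.

## Numerical and degenerate-input conventions

- Coordinates are (x = column, y = row), 0-based, pixel centres at
  integers; all radii and tolerances in pixels.
- Strict inequalities are kept exactly where the algorithms state them:
  inlier distance < TDP, joint-fit D < TDS, support pair distance
  rejected when < K, suppression keeps |S − S*| > K, completion > TL,
  match IoU > 0.8.
- Suppression ties (equal point counts) break on the lexicographically
  smallest (y, x) point, making every stage's output independent of
  input order.
- Empty and constant images yield empty edge maps, not errors; images
  smaller than one patch yield no detections.
- The noise sweep seeds each (σ, repetition) cell independently of the
  number of repetitions requested, so any single repetition is
  reproducible in isolation.

## Known limitations

- Circles smaller than r ≈ 8 px rarely reach m_min = 16 support points
  and are below the method's design range (10–100 px).
- Circles extending into a non-stride-aligned border strip lose the
  support that falls there; completion may then reject them.
- A thin stroked ring (hairline circle) is two intensity edges ~2 px
  apart; below r ≈ 45 the tolerance clamp prevents their fusion and two
  concentric detections result. Filled or annular structures do not
  exhibit this.
- Runtime grows with spurious edge density; the patch budget cap (10⁵)
  bounds the worst case but dense-noise patches are slow.
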