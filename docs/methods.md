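# Methods

## Generative model

Each nucleus carries one promoter that follows a two-state continuous-time
Markov chain: OFF -> ON at rate `k_on` (1/s), ON -> OFF at rate `k_off`
(1/s). The chain is sampled exactly by drawing exponential holding times; no
time-step approximation is involved. The per-frame state is the state at the
frame *midpoint*, which avoids the edge bias of start-of-frame sampling at
moderate rates but — like any frame sampling — cannot see dwells shorter
than the frame interval (see *Rate recovery* below).

While ON, transcripts initiate as a Poisson process at `loading_rate`
(transcripts/s). Each nascent transcript contributes fluorescence for a
fixed `transcript_dwell_s`; the dot's transcript count at a frame is the
number of initiation events in the trailing dwell window. This deterministic
dwell-window model is one deliberate simplification among several possible
intensity kinetics (full elongation models track polymerase positions); it
reproduces the feature the pipeline measures — intensity fluctuations
coupled to promoter state — without extra parameters, and it is isolated in
`simulate_telegraph` so it can be swapped.

Mitosis is modeled as a reset: at every stage boundary all promoters return
to OFF (or ON with probability `p_init_on`), the transcript clock restarts,
and nucleus home positions are re-jittered. No lineage is tracked; the
analysis restarts tracking per stage, so lineage would be unobservable
anyway.

### Rendering

The green channel is a sum of isotropic 2D Gaussians (width `psf_sigma_px`),
one per dot, with amplitude `amp_per_transcript x transcript_count x
bleach(t)`, over a uniform `background_level`, plus i.i.d. Gaussian read
noise (`noise_sd`); Poisson shot noise is available behind a flag but off by
default — read noise alone is sufficient for the threshold-robustness
properties being tested. Bleach decay is `2^(-t / bleach_halflife_s)` and is
applied to signal (dots, nuclei), not to the background offset. Optional z
planes render defocused, energy-attenuated copies of each dot; the default
stack is 3 planes. The red channel renders nuclei as filled disks at their
per-stage home positions. Output is 8-bit by default, because the detection
threshold (55) is defined on the 8-bit scale; 16-bit output is supported and
is linearly rescaled by 1/257 at the detection boundary.

### Default geometry and kinetics

Defaults emulate super-resolution acquisition of a syncytial blastoderm
field: frame interval 1.77 s, 0.5 um z step. The simulated field is
256 px with a 4x4 nucleus grid — a scaled-down field that preserves what the
analysis actually depends on, the ratio of inter-nucleus spacing (64 px) to
the tracking link distance (15 px) and to the PSF width (1.5 px). Kinetic
defaults `k_on = 0.02/s`, `k_off = 0.05/s` give ~20 s bursts separated by
~50 s gaps, i.e. several bursts per nuclear cycle at a ~30% duty
cycle; `loading_rate = 0.2/s` with a 50 s dwell gives ~10 nascent
transcripts at steady state.

## Pipeline conventions

* **Projection / bleach correction.** Maximum-intensity projection over z;
  all arithmetic in float64, with conversion to uint8 (clip + round) only
  immediately before detection. Default bleach correction is `simple_ratio`
  (scale every frame's mean to the frame-0 mean) — the lightest
  CorrectBleach-style mode and robust on short stage movies; the
  `exponential_fit` alternative fits `a*exp(-b t) + c` to frame means and
  falls back to `simple_ratio` with a warning when the fit fails. Correction
  is whole-movie by default; apply it per stage by correcting the split
  outputs. JPEG export exists in no quantitative path: lossy frames corrupt
  area and brightness metrics.
* **Detection.** Strict `>` at the threshold (a convention must be chosen;
  it is documented and bit-exact), 8-connectivity default, no minimum-area
  filter by default. Brightness is the mean original intensity over the
  *filled* component. Per-stage min–max normalization pools every dot of the
  stage across frames of one movie (not across movies); a degenerate stage
  (max = min) maps to 0 to keep the [0, 1] contract. Nuclear masking (Otsu
  on red + hole fill, drop dots with centroids outside) is available but off
  by default — the baseline procedure is a pure green-channel threshold.
* **Tracking.** Greedy nearest-centroid linking in ascending distance order,
  ties broken toward the lower (older) track ID for determinism; optimal
  (min-total-distance) per-frame assignment is available for dense fields
  and agrees with greedy whenever candidates are unambiguous. The default
  link distance of 15 px and gap tolerance of 10 frames are configurable and
  logged: the gap tolerance is what lets a bursting nucleus keep one ID
  through dark frames, and setting it to 0 recovers strict previous-frame
  linking. Tracking restarts at every stage boundary; IDs are per-stage and
  sequential by creation.
* **Metrics.** A *burst* is a maximal run of consecutive frames in which a
  track's dot is detected. Stage metrics use: moving-average smoothing
  window of 3 frames before first-peak calling (suppresses single-frame
  flicker); an "initiation window" of the first 25% of stage frames starting
  at first detection (`init_window_frac`, configurable — no canonical
  definition exists); "average transcription rate" proxied by the stage mean
  of per-frame mean dot area; "intensity peak SD" as the SD across tracks of
  each track's maximum brightness. All times are seconds, sizes pixels.
  Dispersion is sample SD (n-1) and SEM = SD/sqrt(n); a single value yields
  NaN, flagged rather than zero.

### Rate recovery

Averaging detected run lengths overestimates mean dwell times: runs shorter
than the frame interval are invisible, and sub-frame gaps merge adjacent
runs. `estimate_switching_rates` therefore inverts the exact transition
probabilities of the sampled two-state chain,

    p01 + p10 = 1 - exp(-(k_on + k_off) dt),
    k_on / (k_on + k_off) = p01 / (p01 + p10),

pooling frame-to-frame transitions over tracks. This is consistent under
discretization; standard errors come from the binomial errors of the
transition fractions via the delta method. Mean ON/OFF durations are
reported as 1/k_off and 1/k_on. Raw presence-run durations remain available
in `track_features` for the regime where dwells are long relative to the
frame interval.

## Statistics

The unit of the headline comparisons is the movie (embryo); per-track
pooling is available (`unit: track`) but labeled exploratory, since tracks
within a movie are not independent.

* **Mann–Whitney U**: midrank ties; exact enumeration when
  n1 + n2 <= 12 and tie-free, else the normal approximation with tie and
  continuity corrections (scipy backend; tests verify it against full
  enumeration).
* **Permutation test** (mean difference): the alternative's direction is set
  by the sign of the observed difference, reproducing the described
  procedure exactly. This data-dependent rule rejects at roughly twice the
  nominal level under the null (it is equivalent to taking the smaller
  one-sided p), so every result also carries the two-sided p, and the
  calibration test asserts the two-sided p holds its level. Exact
  enumeration up to 20,000 arrangements, else Monte Carlo (default 10,000
  draws, mandatory seed) with the observed arrangement included in numerator
  and denominator, so exact p >= 1/N and never 0.
* **t-test**: a two-sided F-test of variance equality at alpha = 0.05 gates
  between the pooled (Student) and Welch (Satterthwaite) forms; the chosen
  branch is recorded. The F-test is the gate because it is the classical
  variance-significance test; Levene (Brown–Forsythe, median-centered) is
  available in `variance_compare` for heavy-tailed data.
* No multiple-testing correction is applied anywhere; results tables carry
  raw p-values and a star coding with ns > 0.05.

## What the simulator does and does not establish

Passing the validation battery shows the pipeline is *internally correct*:
detection is exact on clean renders and matches a flood-fill oracle,
tracking preserves identity under jitter and blinking, run-length and rate
metrics recover the generative parameters, and the tests hold their nominal
levels. The simulator does not emulate: chromatin-proximity pairing of dots,
uneven illumination or camera fixed-pattern noise, nuclear crowding and
collisions at nc14 densities, z-drift, dot splitting/merging optics, or
elongation-coupled intensity ramps. Results on real movies therefore still
need the usual visual spot checks (overlay of tracks on frames) before
biological interpretation.

### Validation problem sizes

The end-to-end checks run at deliberately compact sizes chosen to be
statistically decisive: 9-nucleus/50-frame noise-free fixtures for detection
exactness; 20 jittered fixtures for tracking; 50 tracks x 2,000 frames for
rate recovery; 1,000 enumeration cases and 2,000 null datasets for the
statistics; and for the directional power check, 7 movies per condition with
16 nuclei and a 400-frame (~12 min) stage. The power fixture uses a 2 s
signal dwell with a 5/s loading rate: presence-run burst calling reflects
promoter switching only when the fluorescence dwell is short against burst
durations — with a long dwell the dot stays lit long after switch-off and
burst frequency decouples from k_off, which would make the check measure
dwell kinetics instead of bursting.

## Known limitations

* One dot per nucleus by construction; sister-chromatid double dots and
  transvection pairing are out of scope.
* Detection has no sub-pixel localization and no splitting of merged
  components; at real nc14 densities the default parameters will merge
  neighbors, and the optimal-assignment tracker plus a nuclear mask are the
  mitigations offered.
* Stage boundaries are user input; there is no automatic anaphase detection.
* Telegraph-rate estimation assumes the two-state model and stationarity
  within a stage; it is a summary, not a fitted HMM.
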