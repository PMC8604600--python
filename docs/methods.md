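# Methods

## Model and assumptions

The package implements a keyed perceptual hash for grayscale diagnostic
images.  The working assumptions are:

* the protected content lives in the coarse and mid-frequency wavelet
  structure of a 512×512 frame; ordinary signal processing perturbs
  coefficients by amounts small against a quantization step of Δ = 20, while
  meaningful tampering moves many coefficients across steps;
* robustness is created *before* compression, by dither quantization and by
  binarizing against a robust location statistic (the trimean), so that
  outlier coefficients cannot move the threshold;
* security comes from key-dependence at three points — the ±1 dither matrix,
  the cat-map coordinate scrambling, and the bit-level scrambling — all
  derived deterministically from one passphrase through the logistic map.

Any RGB input collapses to luminance (0.299/0.587/0.114) and is
bilinear-resized to 512×512 before hashing; 8- and 16-bit rasters are
accepted.

## Parameters

| parameter | default | meaning |
|---|---|---|
| Δ (`delta`) | 20 | base quantization step, in coefficient units of the Haar transform; sets the robustness/fragility balance |
| β (`beta`) | 0.1 | jitter factor; steps range over [Δ(1−β), Δ(1+β)], keying the quantizer while keeping steps positive (β < 1) |
| λ | 3.99 | logistic-map parameter; fixed inside the chaotic regime. 4.0 is avoided because it maps x = 0.5 to the absorbing fixed point 0, which would degrade some passphrase seeds |
| burn-in | 100 | logistic iterates discarded before the orbit is used, to escape transients |
| q | 5 | cat-map scrambling rounds; the key space is (N−1)^2q |
| N | 128 | side of the canonical content-level feature matrix (LL2 of a 512×512 frame); level-1 features are 256×256 and reuse (a, b) reduced mod N−1 |
| threshold | 0.15 | normalized Hamming distance separating authentic from tampered; an empirical choice on the synthetic corpus, not a derived constant |

The passphrase-to-key pipeline is fixed as: mean ASCII code ÷ 128 → logistic
seed; 50 iterations; the next two iterates expanded by 10⁶, reduced mod
N−1 and shifted into [1, N−1] to give (a, b).  The iteration count and
expansion constant are conventions of this implementation (the underlying
scheme only prescribes "iterate, expand, reduce, round"), so hashes are
comparable only between parties using this package.

## Numerical choices

* **Wavelet**: Haar, two levels.  Orthogonal and exact on dyadic sizes, so
  the reconstruction round-trip holds to < 1e−8 and subband shapes halve
  cleanly (512 → 256 → 128).
* **Rounding**: the quantizer rounds ties half away from zero, giving a
  symmetric, platform-independent error bound |L − E₀| ≤ Q<sup>d</sup>/2 and
  exact idempotence.
* **Dither threshold**: orbit values ≥ 0.5 map to +1, else −1.
* **Quantile rule**: the p-quantile is the order statistic x₍⌊np⌋₊₁₎ when np
  is fractional and the midpoint (x₍np₎ + x₍np+1₎)/2 when np is integral
  (ends clamped); the median is the n-odd/n-even special case.  The quartile
  spread is (Q₃ − Q₁)/1.349, normal-consistent for a standard deviation.
  The spread is recorded in hash metadata but does not enter the bits, since
  both compression schemes consume bit matrices.
* **Binarization**: strict inequality against the matrix's own trimean, so a
  constant matrix deterministically binarizes to all zeros.
* **Scheme 2 blocks**: a level is partitioned into exactly 40 blocks.  A
  plain 20×20 tiling is used whenever the level's dimensions tile into
  exactly 40 such blocks; otherwise an 8-column × 5-row grid of near-equal
  rectangles (the canonical 128×128 and 256×256 levels fall in this case —
  no feature level of a 512×512 frame tiles into 40 blocks of 20×20, so the
  printed 120-bit contract is treated as normative and the grid follows it).
  Majority ties count as 0.
* **Scheme 1 serialization**: row-major, 6-decimal fixed point, negative
  zero collapsed; the first 40 MD5 digest bits are kept per level so both
  schemes meet the same 40-bit contract.  MD5 is applied to the scrambled
  binarized feature — the "robust feature" — so the exact hash inherits
  whatever stability the binarization provides.
* **Bit scrambling**: each level's 40 bits are permuted by indices
  ⌊x·40⌋ drawn from the keyed logistic orbit, duplicates skipped, with a
  deterministic fill if the orbit degenerates; the permutation is exactly
  invertible.
* **Optical key**: k₁ is encoded as 64-bit two's-complement fixed point with
  32 fractional bits, tiled to the base key length and XORed.  The
  derivation uses no pixel data, so image processing cannot change it;
  estimating k₁ (e.g. from calibration metadata) is out of scope and it is
  accepted as configuration.

## Synthetic data

`generate_test_image` emulates a microscopy-like diagnostic frame: a smooth
illumination gradient, ~140 sharp-rimmed cell-like disks (sigmoid rim,
softness 1.2 px, amplitude 35–80 gray levels of either sign), and
band-limited speckle (Gaussian noise smoothed at σ = 0.8 px).  The sharp
rims and speckle matter: they give the quantized detail energies
non-degenerate statistics (≈80% of E₁ cells and ≈98% of E₂ cells nonzero),
as in real stained-smear frames.  What the generator does **not** emulate:
optical blur and vignetting, stain variability, correlated sensor noise,
anatomy-specific structure.  Passing tests therefore demonstrate the
pipeline's mechanics and its statistical separation on texture-rich frames,
not clinical performance on real acquisitions.

Attack fixtures cover JPEG recompression (Pillow round-trip), seeded
additive Gaussian noise, mean filtering, and rectangular block tampering.

The two clinical tables (paired bleeding volumes; paired recovery scores;
control vs test group, 40 records each) are packaged verbatim as CSV, values
unitless as printed in their source, with stored MD5 digests guarding the
transcription.  The source reports no derived statistics for them, so the
package exposes descriptive summaries only; a rank-based comparison lives in
`scripts/clinical_demo.py` as a demo, not API.  The source text mentions 80
patients and 90 controls while printing 40 records per group; the tables are
shipped as printed and the discrepancy is documented here, not resolved.

## Measured behaviour and known limitations

All numbers below are recomputed by `scripts/acceptance.py` and the test
suite; none are hard-coded.

* **Scheme 2 (block majority)** separates content-preserving processing from
  distinct content clearly: on the 50-frame corpus the mean normalized
  distance under JPEG-70 is ≈ 0.10–0.11 against ≈ 0.20–0.22 between distinct
  frames.
* **Scheme 1 (exact MD5) has no robustness margin.**  JPEG-70 always flips
  at least one cell of a ~16k-cell binarized feature; MD5's avalanche then
  decorrelates the digest completely, so the distance under JPEG-70 and the
  distance between distinct frames share the same population mean of 0.5.
  The corpus test asserting a strict separation of those means for Scheme 1
  is retained and fails — the measured gap (≈ 0.507 vs ≈ 0.499) is sampling
  noise, and a passing run would be luck, not robustness.  Scheme 1 is an
  integrity hash, not a perceptual one: it is the right choice only when
  bit-exact feature stability is expected.
* **Key sensitivity differs by scheme.**  Under Scheme 1, different
  passphrases move the hash to coin-flip distance (mean ≈ 0.48–0.51), as an
  exact hash should.  Under Scheme 2, majority coding concentrates each bit
  on the sign of (block one-fraction − ½), and the one-fraction of a
  trimean-binarized feature is nearly key-invariant (≈ 0.40–0.50 per level,
  set by the feature distribution's skew); many bits are therefore identical
  under every key and the mean key-pair distance is ≈ 0.15–0.23 rather than
  0.5.  Different passphrases still change the hash in almost every pair,
  but Scheme 2's security margin is the smaller one.
* The default verification threshold 0.15 does not cleanly separate every
  attack: strong JPEG recompression of some frames exceeds it, and small
  tampered regions (a few percent of the frame) can fall under it.  The
  threshold is configurable per deployment and should be calibrated on the
  imaging pipeline in use.
* The chaotic key derivation (logistic map, ASCII mean seeding) is
  deterministic chaos, not cryptography: it has no collision resistance or
  key-stretching properties, and the effective seed space of short
  passphrases is small.  Deployments needing cryptographic keys should
  derive the passphrase digest with a real KDF upstream and feed the result
  in as the passphrase.
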