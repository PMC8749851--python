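# stridesense

Stride-length estimation from foot-mounted inertial measurement units (IMUs)
during maximal linear sprint acceleration.

Athletes surpass 5 m·s⁻¹ within a few strides of a sprint start, beyond the
speed range where foot-worn-sensor stride lengths have traditionally been
validated. The obstacle is the touch-down impact: the landing produces large
acceleration peaks in the first ~20 ms of ground contact that, once
integrated, leave a spurious constant offset in the horizontal velocity of
the foot and wreck the double-integration estimate of stride length. This
package implements a zero-velocity-update scheme that removes that offset by
exploiting the amortisation phase of early stance — the short window in
which the foot is momentarily at rest even at sprint speeds — together with
the surrounding machinery: orientation filtering, gait-event detection, a
synthetic sprint simulator with exact ground truth, and agreement
statistics.

## The algorithm

A stride runs from touch-down (TD) of one foot to the next TD of the same
foot. Per stride, on each horizontal global-frame axis independently:

1. **Integrate** the unfiltered acceleration (cumulative trapezoid, zero
   initial velocity) to the *original* velocity `v`; mirror the axis if the
   mean velocity is negative.
2. **Guard**: copy `v`, set the first 20 ms to `v(20 ms) + 1 m·s⁻¹`, and
   low-pass at 40 Hz (zero phase) → the *temporary* velocity, guaranteed to
   decline after 20 ms.
3. **Offset search**: the minimum of the temporary velocity 20–100 ms after
   TD (20–160 ms for stride 2, whose contact is the longest) is the
   touch-down velocity offset `v_off` at index `i_off`.
4. **Zero-velocity update**: `v_final(i) = 0` for `i < i_off`,
   `v(i) − v_off` otherwise.
5. **Integrate** `v_final` to the displacement `(dx, dz)`; stride length
   `SL = √(dx² + dz²)`, stride speed `SL / duration`.

The first stride of each foot has no preceding TD (standing start):
integration starts 280 ms before the first toe-off with zero initial
velocity and no correction. Orientation (sensor → global frame, y up) comes
from a gradient-descent complementary (Madgwick) filter with gain
β = 0.043; TD/TO instants are detected from the medial–lateral gyroscope
axis. Agreement against a reference is summarized as Bland–Altman bias ±
limits of agreement with a one-way random-effects variance partition over
participants (repeated measures).

## Worked example

```sh
stridesense simulate --effort 100 --fs 500 --seed 1 --out demo/
stridesense process --input demo/sprint_left.csv --effort 100 --out demo/strides.csv
```

`demo/strides.csv` then holds one row per stride, e.g. (seed 1, left foot,
selected columns):

```
stride_index  duration_s  length_m  speed_m_s  offset_vx_m_s
1             0.664       0.948     1.427
2             0.550       2.213     4.023     -0.491
3             0.512       2.816     5.499     -0.463
4             0.492       3.164     6.431      0.399
...
11            0.454       3.738     8.234      0.487
```

Stride lengths grow from ~0.95 m out of the blocks to ~3.7 m near maximal
speed; `offset_vx_m_s` is the spurious touch-down velocity offset that was
removed per stride (stride 1 has none), and the maximal stride speed here
(8.23 m·s⁻¹) sits just below the profile's 8.4 m·s⁻¹ ceiling, as it should
for a stride-mean speed. The ground truth for this sprint is in `demo/truth.json`; comparing
column `length_m` against it gives per-stride errors well below 1%.

Detect events from a gyroscope trace and compare two stride tables:

```sh
stridesense events --input gyro.csv --out events.json
stridesense agree --imu strides.csv --ref reference.csv --by effort --out report.json
```

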