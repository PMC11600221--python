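"""Simulate an electronic-tongue measurement and encode it as a GAF image.

Builds one synthetic 7-wine dataset (15 differential-voltage channels, 100 s
reference + 60 s test at 1 Hz), concatenates the test window of the first
measurement into the 900-point spectrum-like vector, and renders its Gramian
Angular Field fingerprint at 96x96.
"""

import numpy as np

import gafsense as gs

dataset = gs.generate_task_dataset("wine", gs.SimulationConfig(seed=1))
rec = dataset.recordings[0]
print(f"dataset: {len(dataset)} measurements, classes {sorted(set(dataset.labels))}")
print(f"first recording: {rec.n_channels} channels x {rec.n_samples} s, label {rec.label!r}")

window = gs.extract_test_window(rec)
signal = gs.concatenate_channels(window)
print(f"test window {window.shape} -> concatenated vector of {signal.n} points")

reduced = gs.paa_reduce(signal.values, 96)
norm = gs.minmax_normalize(reduced)
g = gs.gaf(gs.to_polar(norm))
print(f"GAF matrix {g.matrix.shape}, entries in [{g.matrix.min():.3f}, {g.matrix.max():.3f}]")
# the diagonal encodes the signal: G_ii = 2 x_i^2 - 1
assert np.allclose(np.diag(g.matrix), 2 * norm.values**2 - 1)

img = gs.render_image(g, 96)
star = gs.encode_recording(rec, encoding="GAF*")
print(f"rendered {img.pixels.shape} fingerprint; GAF* differs in "
      f"{np.mean(img.pixels != star.pixels):.0%} of pixels (amplitude re-weighting)")
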