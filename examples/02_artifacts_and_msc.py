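"""Screen air/lid artifact scans and correct light scattering with MSC.

Injects known artifact scans into a clean simulation, shows that the
correlation/absorbance screen finds exactly those scans, then applies
multiplicative scatter correction and reports how much per-scan
variability it removes.
"""

import numpy as np

from woodvar import SimulationConfig, generate_dataset, nested_decomposition
from woodvar.preprocess import detect_artifact_scans, drop_flagged, msc
from woodvar.simulate import inject_artifacts

cfg = SimulationConfig(n_lots=4, n_scans_per_replicate=30, seed=3)
clean, _, _ = generate_dataset(cfg)
spiked, injected = inject_artifacts(clean, rate=0.02, kind="mixed", seed=11)
print(f"injected {len(injected)} artifact scans into {spiked.n_scans}")

flags = detect_artifact_scans(spiked)
found = set(np.flatnonzero(flags))
print(f"detector flagged {len(found)} scans; "
      f"recall = {len(found & set(injected)) / len(injected):.2f}, "
      f"precision = {len(found & set(injected)) / len(found):.2f}")

filtered, dropped = drop_flagged(spiked, flags)
labels = filtered.labels[["lot", "subsample", "replicate"]]
pre = nested_decomposition(filtered.absorbance, labels)
corrected, model = msc(filtered)
post = nested_decomposition(corrected.absorbance, labels)
print(f"\nscan-level mean MSQ before MSC: {np.mean(pre.msq['scan']):.3e}")
print(f"scan-level mean MSQ after  MSC: {np.mean(post.msq['scan']):.3e}")
print("the drop is the multiplicative/offset scatter MSC removed; the fitted")
print(f"per-scan slopes span [{model.slope.min():.2f}, {model.slope.max():.2f}]")
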