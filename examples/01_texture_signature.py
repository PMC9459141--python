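"""Extract the 14-feature radiomic signature from synthetic textured volumes.

Generates a few masked grayscale volumes per class (benign = smooth
correlated field; malignant = same field plus high-frequency
heterogeneity), computes the wavelet/GLCM/GLSZM/GLDM/first-order
signature for each, and shows which feature separates the classes.
"""

import numpy as np
from scipy import stats

from trusrad.synthetic import gen_roi_volumes
from trusrad.texture import ExtractionConfig, extract_table

rois = gen_roi_volumes(n_per_class=10, shape=(16, 16, 16), seed=7)
table = extract_table(rois, ExtractionConfig(bin_width=25.0, wavelet="haar"))

print(f"{len(table)} volumes, {len(table.columns) - 1} signature features\n")
print("feature                                         benign     malignant   MWU p")
for col in table.columns:
    if col == "label":
        continue
    b = table.loc[table.label == 0, col]
    m = table.loc[table.label == 1, col]
    p = stats.mannwhitneyu(b, m, alternative="two-sided").pvalue
    print(f"{col:<46} {b.mean():>9.3g}  {m.mean():>9.3g}   {p:.3g}")

# Texture features (zone entropy, cluster prominence) respond to the
# injected heterogeneity; a small Mann-Whitney p marks class separation.
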