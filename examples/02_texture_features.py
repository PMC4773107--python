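"""Extract the 12 texture features from a segmented lesion.

The VOI is quantized once into 64 grey levels; features come from the
histogram (SUV entropy), the co-occurrence matrix (entropy, uniformity,
dissimilarity, homogeneity), the neighborhood grey-tone difference matrix
(coarseness, busyness, contrast, complexity), and the size-zone matrix
(GLNU, ZSNU, HGLZE).
"""

from pettex import (
    PhantomConfig,
    adaptive_threshold_segment,
    extract_all,
    generate_phantom,
    measure_background,
)

volume, seed_mask, bg_mask = generate_phantom(PhantomConfig(seed=11))
seg = adaptive_threshold_segment(volume, seed_mask,
                                 measure_background(volume, bg_mask))
features = extract_all(volume, seg)

for name, value in features.as_dict().items():
    print(f"{name:>13}: {value:12.6g}")

# Entropies grow with within-tumor heterogeneity; a perfectly flat lesion
# would give entropy 0, uniformity/homogeneity 1 and contrast 0. High
# coarseness means large uniform patches (a "smooth-looking" tumor).
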