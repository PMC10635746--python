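"""Preprocess one phantom and extract its GLCM texture features.

The front end is the standard mammography chain: 3x3 median filtering
(impulse-noise removal), histogram equalization over the full dynamic range,
then a 16-level gray-level co-occurrence matrix at distance 1 averaged over
the four standard angles.  The printed features are the inputs the MLP
classifier consumes; note how contrast and dissimilarity are higher for the
spiculated (malignant) phantom.
"""

import mldstnet as m

spec = m.GLCMSpec()
for cls in ("benign", "malignant", "ignorant"):
    img, _ = m.generate_phantom(m.PhantomSpec(class_label=cls, seed=7))
    img = m.median_filter(img, window=3)
    img = m.equalize(img)
    feats = m.haralick_features(m.compute_glcm(img, spec), spec)
    print(f"{cls:<10} contrast={feats['contrast']:6.3f}  "
          f"dissimilarity={feats['dissimilarity']:5.3f}  "
          f"energy={feats['energy']:6.4f}  entropy={feats['entropy']:5.3f}")

print(f"\nfeature vector has {len(m.FEATURE_NAMES)} named statistics:")
print(", ".join(m.FEATURE_NAMES))
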