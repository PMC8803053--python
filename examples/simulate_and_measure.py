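"""Generate a synthetic adipose region, train the classifier, measure it.

Builds a 2×10⁶ µm² H&E-like field of ≈300 adipocytes with known per-cell
areas, trains the fat/tissue pixel classifier from sampled scribbles, runs
the create-objects pipeline and prints the morphometry summary next to the
ground truth.
"""

import adipoquant as aq

# A validated-scale field: 2000×1000 µm at 150 cells per 1e6 µm².
spec = aq.TissueSpec(seed=7)
image, truth = aq.generate_tissue(spec)
print(f"generated {truth.true_count} cells over {spec.region_area_um2/1e6:.1f}e6 µm²")

# Train on a *different* region so the measured field is unseen.
train_img, train_truth = aq.generate_tissue(aq.TissueSpec(seed=1000))
scribbles = aq.annotations_from_truth(train_img, train_truth, n_per_class=500, seed=1)
model = aq.train_classifier([(train_img, scribbles)], working_pixel_size_um=2.0, seed=0)
print(f"classifier out-of-bag pixel accuracy: {model.oob_accuracy:.4f}")

# Classify, create objects (min object 20 µm², min hole 30 µm², split), filter
# to the 500–100,000 µm² adipocyte range and summarise.
mask = aq.classify_pixels(model, image)
objects = aq.mask_to_objects(mask)
summary = aq.summarize(objects, roi_area_um2=truth.roi_area_um2)

true_areas = truth.cell_areas_um2
true_areas = true_areas[(true_areas >= 500) & (true_areas <= 100000)]
print(f"count:    measured {summary.count}  true {truth.true_count}")
print(f"area:     measured {summary.mean_area_um2:.0f} ± {summary.sd_area_um2:.0f} µm²  "
      f"true {true_areas.mean():.0f} µm²")
print(f"diameter: measured {summary.mean_diameter_um:.1f} ± {summary.sd_diameter_um:.1f} µm")
print(f"density:  {summary.density_per_1e6um2:.1f} cells / 1e6 µm²")
# The diameter is the mean of per-cell circular-equivalent diameters
# 2·sqrt(A/π); density divides the count by the annotated ROI area.
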