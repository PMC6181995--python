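"""Quantify per-cell endocytic uptake in synthetic wide-field images and
compare two conditions with the Mann-Whitney U test.

Two cell fields are generated: a control and a 'treated' field with 1.6x
the mean uptake. Per-cell integrated intensities (background-subtracted
over each cell's label mask) are normalized to the control mean and
summarized the way uptake box plots are drawn: median, quartiles, s.d.
"""

import numpy as np

import cgtension as cg

ctrl = cg.gen_cell_field(n_cells=15, mean_uptake=5e4, cv=0.3, noise_sd=2.0,
                         shape=(448, 448), seed=1)
treat = cg.gen_cell_field(n_cells=15, mean_uptake=8e4, cv=0.3, noise_sd=2.0,
                          shape=(448, 448), seed=2)

ctrl_vals = np.array([r.integrated_intensity
                      for r in cg.measure_uptake(ctrl.image, ctrl.labels)])
treat_vals = np.array([r.integrated_intensity
                       for r in cg.measure_uptake(treat.image, treat.labels)])

fold = cg.normalize_to_control(treat_vals, ctrl_vals)
box = cg.summarize_box(fold)
print(f"treated fold change: median {box.median:.2f} "
      f"[q25 {box.q25:.2f}, q75 {box.q75:.2f}], sd {box.sd:.2f}, n {box.n}")

test = cg.mann_whitney(treat_vals, ctrl_vals)
print(f"Mann-Whitney U = {test.U:.0f} ({test.method}), "
      f"two-sided p = {test.p_two_sided:.2e}")
# median fold ~1.6 recovers the programmed effect; p << 0.001 at n = 15+15
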