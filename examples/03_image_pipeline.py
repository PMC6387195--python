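"""Render simulated cells to a synthetic image and quantify it back.

Simulated per-cell counts are rendered as Gaussian spots inside
non-overlapping cell discs (page 0 carries the cell-label masks, pages 1-2
the C1/C2 probe channels).  Quantification segments the label page, runs
Laplacian-of-Gaussian spot detection per channel, and assigns each spot to
the cell containing it.  Noise-free, the pipeline must return the exact
input counts; with noise it still recovers nearly all well-separated spots.
"""

from deltascope import (
    ImageSpec,
    get_preset,
    grid_layout,
    quantify_image,
    render_image,
    simulate_counts,
)

params = get_preset("BRCA1_carrier", seed=11)
_, counts = simulate_counts(params, 50, sample="sim")
side = 8 * 44 + 8
spec = ImageSpec(width=side, height=side, cell_layout=grid_layout(50, side, side))

stack, truth = render_image(counts, spec, seed=3)
print(f"rendered {len(truth)} spots over 50 cells into a {stack.shape} stack")

quantified, qc = quantify_image(stack, sample="sim")
exact = sum((q.c1, q.c2) == (c.c1, c.c2) for q, c in zip(quantified, counts))
print(f"noise-free quantification: {exact}/50 cells exactly recovered")
print(qc.render())

noisy_spec = ImageSpec(
    width=side, height=side, cell_layout=grid_layout(50, side, side),
    spot_amplitude=1000.0, noise_sigma=100.0,
)
noisy_stack, _ = render_image(counts, noisy_spec, seed=3)
noisy_counts, _ = quantify_image(noisy_stack, sample="sim")
exact_noisy = sum(
    (q.c1, q.c2) == (c.c1, c.c2) for q, c in zip(noisy_counts, counts)
)
print(
    f"at amplitude/noise = 10: {exact_noisy}/50 cells exactly recovered "
    "(detection is thresholded at 6 robust-noise units of the band-pass "
    "response)"
)
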