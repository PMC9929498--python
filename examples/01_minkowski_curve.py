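"""Measure one synthetic egg with the threshold-sweep Minkowski functionals.

Builds a scribbled egg and an equal-marking-area blotched egg, applies the
standard Gaussian smoothing (sigma = 2 px), sweeps 80 intensity thresholds
over each, and prints the integrated summaries.  Σ(P²/A) is the
scribbliness statistic: long thin markings carry far more perimeter per
unit area than compact blotches.  ΣEuler sums components-minus-holes over
the sweep: fewer, connected markings give the lower value.
"""

from minkpat import minkowski_curve, smooth
from minkpat.synth import egg_pair

scribbled, blotched = egg_pair(seed=42)

for name, egg in [("scribbled", scribbled), ("blotched", blotched)]:
    curve = minkowski_curve(smooth(egg, sigma=2), n_levels=80)
    s = curve.summaries()
    print(
        f"{name:9s}  marking area = {egg.meta['marking_area']:5d} px   "
        f"Sum(P^2/A) = {s['sum_p2_over_a']:8.1f}   SumEuler = {s['sum_euler']:6.0f}"
    )

print(
    "\nEqual marking area by construction; the scribbled egg's Sum(P^2/A)\n"
    "far exceeds the blotched egg's, while its SumEuler is lower\n"
    "(5 connected strokes vs 10 separate blobs)."
)
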