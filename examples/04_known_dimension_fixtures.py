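"""Validating the D2 estimators on sets of known dimension.

Generates synthetic point sets / series whose correlation dimension is
known exactly (a point: 0, a line segment: 1, a 2-D patch: 2, a
quasiperiodic ISI series: 1) and checks that both estimators recover it.
"""

from csneuron import estimate_d2_points
from csneuron.fixtures import FIXTURE_KINDS, FixtureSpec, fixture_points

for kind, true_d2 in FIXTURE_KINDS.items():
    n = 10_000 if kind == "uniform_square" else 4000
    emb = fixture_points(FixtureSpec(kind, n_points=n, seed=11))
    line = f"{kind:30s} true D2 = {true_d2:g}  "
    for method in ("correlation_sum", "rotational_spectrum"):
        est = estimate_d2_points(emb, method, n_pairs=100_000, seed=2)
        line += f"{method.split('_')[0]}: {est.d2:.3f}  "
    print(line)
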