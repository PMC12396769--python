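"""Locate the drop value: the detection probability at which the optimal
first observation time jumps away from the horizon.

With two observations and lambda = 1, for small p it is optimal to wait and
take both counts at the horizon (t1* = 1).  Past the drop value the first
count moves abruptly into the interior.  The bisection below brackets that
point for the exact objective to within 1e-3.
"""

from popbp import ModelParams, Schedule, find_drop_values, fisher_information, optimize_schedule

lam = 1.0

def factory(p):
    def ev(times):
        return fisher_information(ModelParams(lam, p), Schedule(times)).value
    return ev

interval = find_drop_values(2, lam, factory, width=1e-3)[0]
mid = 0.5 * (interval.lower + interval.upper)
print(f"drop value bracket: ({interval.lower:.6f}, {interval.upper:.6f})")
print(f"midpoint: {mid:.5f}")
res = optimize_schedule(2, ModelParams(lam, interval.upper), factory(interval.upper))
print(f"just past the drop, optimal times = {tuple(round(t, 5) for t in res.times)}")
# Published computations for this configuration place the drop near 0.91136;
# just past it the first observation jumps from 1 to below 0.5.
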