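#!/usr/bin/env python
"""Division waiting times: assigned versus emergent distributions.

In model 3 polar and non-polar sites draw their waiting times from the
same (non-polar) distribution, yet the *measured* polar waiting time -
from pole formation to polar division - comes out much longer, because
newly formed poles usually start blocked and only activate at a later
re-randomisation.  This script quantifies that emergent gap and the
model-4 prediction that doubled FtsZ shortens minB- waiting times.
"""
import pandas as pd

from mindiv import SimConfig, run, scenario, waiting_time_distribution

OUT = "results/waiting_times.csv"


def summarize(tag, tracking, rows):
    for cls in ("nonpolar", "polar"):
        s = waiting_time_distribution(tracking, site_class=cls)
        if s.n:
            rows.append((tag, cls, s.mean, s.sd, s.n))
            print(f"{tag:14s} {cls:9s} mean {s.mean:6.1f} min  sd {s.sd:5.1f}  n {s.n}")


def main() -> None:
    rows = []
    cfg3 = SimConfig(model_variant=3, strain="minB", n_init=300, t_max=300.0,
                     rng_seed=1)
    r3 = run(cfg3)
    summarize("model3_minB", r3.tracking, rows)
    print(f"  (assigned non-polar mean: {cfg3.dist_params.w_nonpolar_mean} min; "
          "the polar excess is emergent)")
    for name in ("minB", "minB_2xftsz", "wt"):
        cfg = scenario(name, n_init=300, t_max=300.0, rng_seed=1)
        summarize(f"model4_{name}", run(cfg).tracking, rows)
    df = pd.DataFrame(rows, columns=["run", "site_class", "mean_min", "sd_min", "n"])
    df.to_csv(OUT, index=False)
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
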