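"""Draw the survey-shaped synthetic cohorts used by the later steps.

Writes two cohorts under results/: a clean one generated fully from the
unidimensional rating-scale model, and a contaminated one in which the
patient-involvement item (HSE11) is partly driven by a separate trait —
the situation the item-fit step is meant to catch.
"""

import json
from pathlib import Path

import raschclimate as rc

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main():
    OUT.mkdir(exist_ok=True)
    for tag, cfg in {
        "clean": rc.hse_default_config(seed=SEED),
        "contaminated": rc.hse_default_config(
            seed=SEED,
            second_dimension=rc.SecondDimensionSpec(("HSE11",), loading=1.5, trait_sd=1.5),
        ),
    }.items():
        m, factors, truth = rc.simulate_responses(cfg)
        rc.write_responses(m, OUT / f"cohort_{tag}.responses.csv")
        factors.table.to_csv(OUT / f"cohort_{tag}.factors.csv")
        (OUT / f"cohort_{tag}.truth.json").write_text(
            json.dumps(
                {
                    "theta_mean": cfg.theta_mean,
                    "theta_sd": cfg.theta_sd,
                    "delta": list(truth["delta"]),
                    "tau": list(truth["tau"]),
                    "seed": cfg.seed,
                },
                indent=2,
            )
        )
        freq = rc.marginal_frequencies(m)
        print(f"[{tag}] N={m.n_persons}, {m.n_items} items; "
              f"modal categories {freq.to_numpy().argmax(axis=1) + 1}")
    print(f"wrote cohorts under {OUT}")


if __name__ == "__main__":
    main()
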