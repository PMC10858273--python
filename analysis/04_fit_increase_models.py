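"""Fit the Bernoulli escalation models.

Last-vs-first offer per session (condition x session), offer increases after
acceptance vs rejection, and matching the previously accepted offer.  Writes
results/increase_models.json and the per-session contrast table.
"""

import json
from pathlib import Path

from triadic_ug.bayes import SamplerConfig
from triadic_ug.data_model import load_trials
from triadic_ug.models import (
    fit_increase_after_outcome_model,
    fit_last_vs_first_model,
    fit_match_winner_model,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20242


def main() -> None:
    dataset = load_trials(RESULTS / "trials.csv")
    out = {}

    lvf = fit_last_vs_first_model(dataset, SamplerConfig(seed=SEED))
    lvf.tables["per_session"].to_csv(RESULTS / "last_vs_first_per_session.csv", index=False)
    out[lvf.model] = lvf.summary_dict()

    inc = fit_increase_after_outcome_model(dataset, SamplerConfig(seed=SEED + 1))
    out[inc.model] = inc.summary_dict()

    mw = fit_match_winner_model(dataset, SamplerConfig(seed=SEED + 2))
    out[mw.model] = mw.summary_dict()

    (RESULTS / "increase_models.json").write_text(json.dumps(out, indent=2))
    for model, summary in out.items():
        print(model)
        for k, v in summary.items():
            print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
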