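"""Fit the two Beta total-proportional-offer models.

The full-data model contrasts dyadic vs triadic sessions; the first-half model
adds the consecutive vs simultaneous contrast.  Writes posterior-predictive
condition summaries to results/offer_models.json.
"""

import json
from pathlib import Path

from triadic_ug.bayes import SamplerConfig
from triadic_ug.data_model import load_trials
from triadic_ug.models import fit_total_offer_model

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20241


def main() -> None:
    dataset = load_trials(RESULTS / "trials.csv")
    out = {}
    for subset in ("full", "first_half"):
        fit = fit_total_offer_model(dataset, subset, SamplerConfig(seed=SEED))
        out[fit.model] = fit.summary_dict()
        print(f"{fit.model}: n={fit.n_obs}")
        for k, v in fit.summary_dict().items():
            print(f"  {k}: {v}")
    (RESULTS / "offer_models.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
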