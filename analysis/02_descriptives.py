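"""Descriptive statistics of the simulated study.

Reads results/trials.csv and writes results/descriptives.json: mean first
offers per condition, highest-offer acceptance, offer-ratio on responder
errors, and side-choice rates in consecutive trials.
"""

from pathlib import Path

from triadic_ug.data_model import load_trials
from triadic_ug.descriptives import describe

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = load_trials(RESULTS / "trials.csv")
    report = describe(dataset)
    (RESULTS / "descriptives.json").write_text(report.to_json())
    print(report.to_text())


if __name__ == "__main__":
    main()
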