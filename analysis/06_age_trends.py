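"""Age trends in risk taking and learning asymmetry.

Computes each subject's equal-EV risky-choice proportion and fitted
asymmetry index, regresses both on z-scored age with linear and quadratic
terms (nested F arbitration), and certifies u-shapes with the two-lines
test. The cohort generator plants an adolescent peak in the negative
learning rate, so AI should be u-shaped over age (lowest mid-adolescence)
and risky choice should follow the same pattern.
"""

import pathlib

import pandas as pd

from riskrl import agestats, inference, io

BASE = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = 13


def main() -> None:
    data = io.read_trial_table(BASE / "cohort" / "trials.csv")
    truth = pd.read_csv(BASE / "cohort" / "truth.csv").set_index("subject_id")
    out = BASE / "age_trends"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for sid, session in data.items():
        fit = inference.fit_map("RSTD", session, seed=SEED + sid)
        rows.append(
            {"subject_id": sid, "age": float(truth.loc[sid, "age"]),
             "risky_prop": agestats.risky_choice_proportion(session, "equal_ev"),
             "ai": fit.asymmetry_index,
             "alpha_neg": fit.map_params.alpha_neg}
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "subject_measures.csv", index=False)
    print(f"mean equal-EV risky-choice proportion {frame['risky_prop'].mean():.3f}; "
          f"mean fitted AI {frame['ai'].mean():+.3f}")

    tidy = []
    for outcome in ("risky_prop", "ai", "alpha_neg"):
        reg = agestats.quadratic_age_regression(frame["age"].to_numpy(),
                                                frame[outcome].to_numpy())
        quad = reg.quadratic_term()
        two = agestats.two_lines_test(frame["age"].to_numpy(), frame[outcome].to_numpy())
        print(f"{outcome}: quadratic b = {quad['estimate']:+.4f} (p = {quad['p']:.4f}), "
              f"nested F p = {reg.f_p:.4f}, preferred {reg.preferred}; "
              f"two-lines breakpoint {two.breakpoint:.1f}, "
              f"slopes {two.left_slope:+.4f}/{two.right_slope:+.4f}, "
              f"u-shaped: {two.u_shaped}")
        tidy.append(
            reg.quadratic.assign(outcome=outcome, model="quadratic", nested_f_p=reg.f_p)
        )
    pd.concat(tidy).to_csv(out / "age_regressions.csv", index=False)


if __name__ == "__main__":
    main()
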