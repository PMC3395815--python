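"""Validate the fitted model against the experimental intensity table.

Compares capped model predictions at t = 11 min with the measured
avoidance indices at 150-950 lux: error moments, determination
coefficient, and the F-test at the 1% level.

Output: results/validation_report.json
"""

from pathlib import Path

from larvataxis import predict_intensity_response, reference_data, validate_fit
from larvataxis.validation import round_half_up, write_validation_report

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table, params = reference_data()
    _, capped = predict_intensity_response(params, table.intensities, t=11.0)
    quality, errors = validate_fit(table.ai, capped, alpha_level=0.01)

    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "validation_report.json"
    write_validation_report(out, quality, errors, alpha_level=0.01)

    print("model adequacy against the five-intensity experimental table:")
    print(f"  mean error          {round_half_up(errors.mean_error, 2):+.2f}")
    print(f"  std error            {round_half_up(errors.std_error, 2):.2f}")
    print(f"  mean |error|         {round_half_up(errors.mean_abs_error, 2):.2f}")
    print(f"  std |error|          {round_half_up(errors.std_abs_error, 2):.2f}")
    print(f"  R^2                  {round_half_up(quality.r_squared, 2):.2f}")
    print(f"  F = {quality.f_value:.2f} vs F_0.01(1,{quality.n_points - 2}) = "
          f"{quality.f_critical:.2f} -> "
          f"{'passes' if quality.passes_f_test else 'fails'} the F-test")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
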