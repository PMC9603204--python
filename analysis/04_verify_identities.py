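#!/usr/bin/env python
"""Cross-check the arithmetic of the published national tables.

Every identity the published accounting implies among its own printed
numbers -- inventory column sums, cumulative-sink table sums and row
consistency, stock differences vs cumulative sinks, the coverage-driven
afforestation schedule, growth statistics, mitigation averages and
percentage gains -- is recomputed from the packaged tables and compared
at printed one-decimal precision.

Writes results/identities.csv.
"""

from arborcarbon.pipeline import verify_identities


def main() -> None:
    report = verify_identities()
    report.to_csv("results/identities.csv", index=False)
    passed = int(report["passed"].sum())
    print(f"{passed}/{len(report)} published-number identities reproduce at printed precision")
    failed = report[~report["passed"]]
    if not failed.empty:
        print(failed.to_string(index=False))
    else:
        print("largest deviation: "
              f"{(report['computed'] - report['reported']).abs().max():.3f} "
              "(within one-decimal rounding)")
    print("wrote results/identities.csv")


if __name__ == "__main__":
    main()
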