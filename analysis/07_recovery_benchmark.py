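"""How reliably do the two detectors recover a known injected shift?

Replicated simulations (50 seeds) on the fixed 12-taxon benchmark tree
with one heterochronic shift injected on an internal branch.  Reports
recall of event-pair cracking (flag at the injected node) and of the
continuous root-CI criterion (flag at a descendant taxon), at the
default gross effect (6 of 10 positions) and the 4- and 5-position
sensitivity points.
"""

import json
from pathlib import Path

from heterochron.benchmark import run_recovery

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    out = {}
    for shift in (6, 5, 4):
        bench = run_recovery(seeds=50, shift=shift)
        out[f"shift_{shift}"] = {
            "cracking_recall": bench.cracking_recall,
            "continuous_recall": bench.continuous_recall,
        }
        print(f"shift +{shift} positions: cracking recall "
              f"{bench.cracking_recall:.2f}, continuous recall "
              f"{bench.continuous_recall:.2f}  (50 seeds)")
    (RESULTS / "recovery_benchmark.json").write_text(json.dumps(out, indent=2) + "\n")
    print("the conservative t-interval needs >=5 interacting pair changes, so "
          "cracking recall falls off below ~5-position shifts while the "
          "continuous criterion stays saturated")


if __name__ == "__main__":
    main()
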