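"""Map characters on the two hypothesis topologies and compare them.

For each character set (binned, event-pair) and treatment (unordered,
ordered): parsimony length of the molecular and morphological trees and
the two-tailed signed-rank (Templeton-style) test of whether either
topology fits the characters significantly worse.
"""

import json
from pathlib import Path

from heterochron import datasets
from heterochron.chronos import unit_branch_lengths
from heterochron.parsimony import templeton_test, tree_length
from heterochron.seqdata import read_character_matrix

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    mol = unit_branch_lengths(datasets.load_hypothesis("molecular"))
    mor = unit_branch_lengths(datasets.load_hypothesis("morphological"))
    out = {}
    for name in ("binned", "eventpair"):
        matrix = read_character_matrix((RESULTS / f"{name}.tnt").read_text())
        for ordered in (False, True):
            key = f"{name}_{'ordered' if ordered else 'unordered'}"
            lm = tree_length(matrix, mol, ordered).total_length
            lr = tree_length(matrix, mor, ordered).total_length
            t = templeton_test(matrix, mol, mor, ordered)
            out[key] = {
                "length_molecular": lm,
                "length_morphological": lr,
                "templeton_n_nonzero": t.n_nonzero,
                "templeton_W": t.statistic,
                "templeton_p": round(t.p, 6),
            }
            verdict = "no significant difference" if t.p > 0.05 else "significant"
            print(f"{key}: molecular {lm} vs morphological {lr} steps; "
                  f"signed-rank p = {t.p:.4f} ({verdict})")
    (RESULTS / "topology_tests.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
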