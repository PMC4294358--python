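#!/usr/bin/env python
"""Call differentially expressed genes on the synthetic study.

Moderated t-test with BH FDR (alpha 0.05) and a 2-fold-change gate; writes
the per-gene DE table and the summary counts under results/.
"""

from pathlib import Path

from overconnect import load_expression, run_de
from overconnect.diffexpr import write_de_table, write_summary

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "synthetic_study"

if __name__ == "__main__":
    study = load_expression(SIM / "matrix.tsv", SIM / "samples.tsv")
    de, summary = run_de(study, alpha=0.05, fc_threshold=2.0)
    write_de_table(de, ROOT / "de_table.tsv")
    write_summary(summary, ROOT / "de_summary.tsv")
    print(f"{len(de)} genes tested; {summary.n_total_de} significant "
          f"({summary.n_up} up, {summary.n_down} down) at FDR 0.05, FC >= 2.")
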