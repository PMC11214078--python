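"""Steady states of the margin models: wild type vs cuc mutant, PMM vs EMM.

Runs the baseline template through the UTG-only control and both CUC-input
variants, plus the cuc-mutant control, and writes state tables, middle-column
auxin profiles and pattern summaries under results/fig5_states/.
"""

from pathlib import Path

import numpy as np
import yaml

import leafmargin as lm
from leafmargin import io as lmio
from leafmargin.render import render_state_svg

OUT = Path(__file__).resolve().parents[1] / "results" / "fig5_states"


def analyze(tag: str, template, params):
    res = lm.run_to_steady_state(template, params)
    tissue = template.tissue
    field = lm.net_polarity(res.final_state, tissue, params.P_tot)
    profile = lm.column_profile(res.final_state, tissue, tissue.mid_col)
    peaks = lm.detect_emergent_maxima(profile, source_row=2)
    domain = np.nonzero(tissue.cuc > 0)[0]
    n_basal = int(np.sum(field.classes[domain] == "basal")) if domain.size else 0

    outdir = OUT / tag
    outdir.mkdir(parents=True, exist_ok=True)
    lmio.write_state_table(res.final_state, tissue, outdir / "state.csv")
    np.savetxt(outdir / "profile.csv",
               np.column_stack([np.arange(1, profile.size + 1), profile]),
               delimiter=",", header="row,auxin", comments="")
    render_state_svg(res.final_state, tissue, field, outdir / "state.svg")
    summary = {
        "variant": params.variant,
        "scenario": template.name,
        "converged": bool(res.converged),
        "residual": float(res.residual),
        "emergent_maxima": [[int(r), float(a)] for r, a in peaks],
        "basal_cells_in_cuc_domain": n_basal,
        "source_auxin": float(res.final_state.auxin[tissue.source_mask][0]),
    }
    (outdir / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    print(f"{tag:14s} converged={res.converged}  emergent maxima={peaks}  "
          f"basal CUC-domain cells={n_basal}")
    return summary


def main():
    wt = lm.make_template("wt")
    mut = lm.make_template("cuc_mutant")
    print("wild-type template: CUC domain rows",
          sorted(set(wt.tissue.rows[wt.tissue.cuc > 0])))
    for tag, tpl, variant in [
        ("wt_utg_only", wt, "utg_only"),
        ("wt_pmm", wt, "pmm"),
        ("wt_emm", wt, "emm"),
        ("cuc_mutant_pmm", mut, "pmm"),
        ("cuc_mutant_emm", mut, "emm"),
    ]:
        analyze(tag, tpl, lm.ModelParams(variant=variant))
    print(f"\nwrote state tables, profiles and SVG renders under {OUT}")


if __name__ == "__main__":
    main()
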