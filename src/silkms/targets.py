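"""Target-table configuration: read compound/label designs, export tables.

The configuration is YAML with two blocks::

    design:
      tracer: 13C6
      baseline: 15N1
      internal_standard: 2H4      # omit for no IS channel
    half_width: 0.0010            # m/z; optional
    protonated: false             # formulas are cations as given
    compounds:
      - name: IAA-quinolinium
        formula: C9H8N
        rt_window: [4.2, 4.8]
        acquisition: "PRM 176.1"  # optional

For derivatized targets (e.g. methoximated IPyA) the configured formula is
the derivative's ion formula; no derivatization arithmetic is applied.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .chem import DEFAULT_HALF_WIDTH, Formula, IonTarget, LabelScheme, LabelingDesign, build_target_table

__all__ = ["load_target_config", "targets_to_frame", "export_tsv", "export_inclusion_list"]


def load_target_config(path: str | Path) -> list[IonTarget]:
    """Build the target table from a YAML configuration file."""
    doc = yaml.safe_load(Path(path).read_text())
    dsg = doc.get("design", {})
    design = LabelingDesign(
        tracer=LabelScheme.parse(str(dsg.get("tracer", ""))),
        baseline=LabelScheme.parse(str(dsg.get("baseline", ""))),
        internal_standard=(
            LabelScheme.parse(str(dsg["internal_standard"]))
            if "internal_standard" in dsg
            else None
        ),
    )
    compounds = [
        (
            c["name"],
            Formula.parse(c["formula"]),
            tuple(float(x) for x in c["rt_window"]),
            c.get("acquisition"),
        )
        for c in doc["compounds"]
    ]
    return build_target_table(
        compounds,
        design,
        half_width=float(doc.get("half_width", DEFAULT_HALF_WIDTH)),
        protonated=bool(doc.get("protonated", False)),
    )


def targets_to_frame(targets: list[IonTarget]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound": t.compound,
            "channel": t.channel,
            "formula": str(t.ion_formula),
            "label": str(t.scheme),
            "mz": round(t.mz, 6),
            "window_low": t.window.low,
            "window_high": t.window.high,
            "rt_low": t.rt_window[0],
            "rt_high": t.rt_window[1],
            "acquisition": t.acquisition or "",
            "warnings": "; ".join(t.warnings),
        }
        for t in targets
    )


def export_tsv(targets: list[IonTarget], path: str | Path) -> Path:
    path = Path(path)
    targets_to_frame(targets).to_csv(path, sep="\t", index=False)
    return path


def export_inclusion_list(targets: list[IonTarget], path: str | Path) -> Path:
    """PRM-style inclusion list: m/z, charge, RT window start/end (min)."""
    path = Path(path)
    pd.DataFrame(
        {
            "Mass [m/z]": round(t.mz, 4),
            "CS [z]": t.charge,
            "Polarity": "Positive",
            "Start [min]": t.rt_window[0],
            "End [min]": t.rt_window[1],
            "Comment": f"{t.compound} {t.channel} ({t.scheme})",
        }
        for t in targets
    ).to_csv(path, index=False)
    return path
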