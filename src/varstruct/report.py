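"""Static HTML report with side-by-side wild-type / mutant tables."""

from __future__ import annotations

import html

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>varstruct report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin-bottom: 1.5em; }}
th, td {{ border: 1px solid #999; padding: 3px 8px; font-size: 13px; }}
th {{ background: #eee; }}
.changed {{ background: #ffe8d0; }}
</style></head><body>
<h1>Variant structural-impact report</h1>
<p>{meta}</p>
<h2>Cohort summary</h2>
{summary_table}
<h2>Per-variant impact</h2>
{variant_table}
</body></html>
"""


def _table(headers: list[str], rows: list[list], mark_changed: bool = False) -> str:
    out = ["<table><tr>" + "".join(f"<th>{html.escape(h)}</th>" for h in headers)
           + "</tr>"]
    for row in rows:
        cls = ""
        if mark_changed and row and str(row[-1]) == "True":
            cls = ' class="changed"'
        cells = "".join(f"<td>{html.escape(str(c))}</td>" for c in row)
        out.append(f"<tr{cls}>{cells}</tr>")
    out.append("</table>")
    return "\n".join(out)


def render_html(result, header: dict) -> str:
    summary_rows = [[k, v] for k, v in result.summary.items()
                    if k != "per_region"]
    if "per_region" in result.summary:
        summary_rows += [[f"region:{k}", v]
                         for k, v in result.summary["per_region"].items()]
    cols = ["variant", "region", "ss", "burial", "delta_rsa", "hbonds_gained",
            "hbonds_lost", "salt_bridges_gained", "salt_bridges_lost",
            "disulfide_lost", "stability", "conserved_flag",
            "any_structural_change"]
    vrows = []
    for rep in result.reports:
        d = rep.to_dict()
        vrows.append([d[c] for c in cols])
    meta = (f"varstruct {header.get('version', '')} &middot; "
            f"config {header.get('config_hash', '')}")
    return _PAGE.format(meta=meta,
                        summary_table=_table(["quantity", "value"], summary_rows),
                        variant_table=_table(cols, vrows, mark_changed=True))
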