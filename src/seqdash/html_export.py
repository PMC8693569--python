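"""Render widget documents into self-contained HTML.

A rendered widget is a complete HTML document (or an embeddable fragment)
with the runtime script, glue code and styles inlined, plus a JSON "data
island" carrying the widget document bit-exactly.  Standalone files reference
nothing external, so they can be opened anywhere with no server, network or
analysis environment, and re-rendering the same document is byte-identical
(fixed version string, no timestamps).
"""

from __future__ import annotations

import itertools
import json
import os
import re
from dataclasses import dataclass
from importlib import resources

from .data_model import ValidationError
from .widget_spec import SCHEMA_VERSION, WidgetDoc, validate_doc

__all__ = ["RenderedWidget", "render_standalone", "render_fragment", "extract_payload"]

_fragment_counter = itertools.count(1)

_ISLAND_RE = re.compile(
    r'<script type="application/json" class="seqdash-data" id="[^"]*">(.*?)</script>',
    re.DOTALL,
)


def _asset(name: str) -> str:
    return resources.files("seqdash").joinpath("assets", name).read_text("utf-8")


@dataclass
class RenderedWidget:
    """An HTML rendering plus the payload recoverable from it."""

    html_text: str
    embedded_payload: dict
    assets_inlined: bool


def _encode_island(doc: WidgetDoc, container_id: str) -> str:
    payload = json.dumps(
        doc.to_dict(), sort_keys=True, separators=(",", ":"), allow_nan=False
    )
    # escape closing-tag sequences so the island never terminates the script
    payload = payload.replace("</", "<\\/")
    return (
        f'<script type="application/json" class="seqdash-data" '
        f'id="{container_id}-data">{payload}</script>'
    )


def extract_payload(html_text: str) -> dict:
    """Recover the widget document embedded in rendered HTML (bit-exact)."""
    m = _ISLAND_RE.search(html_text)
    if m is None:
        raise ValidationError("no widget data island found in HTML")
    return json.loads(m.group(1).replace("<\\/", "</"))


def _widget_markup(doc: WidgetDoc, container_id: str) -> str:
    island = _encode_island(doc, container_id)
    return f"""<div class="seqdash-widget" id="{container_id}" data-kind="{doc.kind}">
{island}
<div class="seqdash-root"></div>
</div>
<script>seqdashRender("{container_id}");</script>"""


def render_fragment(doc: WidgetDoc) -> RenderedWidget:
    """Render an embeddable HTML fragment with a unique container id.

    The fragment carries the runtime and styles so it works on its own
    inside any host page; ids are sequenced so several widgets coexist in
    one notebook or report.
    """
    validate_doc(doc)
    container_id = f"seqdash-{doc.kind}-{next(_fragment_counter)}"
    html = f"""<style>{_asset("runtime.css")}</style>
<script>{_asset("runtime.js")}</script>
{_widget_markup(doc, container_id)}
"""
    return RenderedWidget(
        html_text=html, embedded_payload=extract_payload(html), assets_inlined=True
    )


def render_standalone(doc: WidgetDoc, path: str | os.PathLike | None = None) -> RenderedWidget:
    """Render a complete standalone HTML document (optionally written to path).

    Everything — runtime JavaScript, styles, interaction glue and the data —
    is inlined; the document makes zero external references.  Save-plot
    buttons export the current panel as PNG or SVG and the save-data button
    emits the annotation + statistics + expression CSV, scoped to the
    selection or to all genes.
    """
    validate_doc(doc)
    container_id = "seqdash-widget"
    html = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>seqdash {doc.kind} widget</title>
<meta name="generator" content="seqdash {SCHEMA_VERSION}">
<style>{_asset("runtime.css")}</style>
<script>{_asset("runtime.js")}</script>
</head>
<body>
{_widget_markup(doc, container_id)}
</body>
</html>
"""
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(html)
    return RenderedWidget(
        html_text=html, embedded_payload=extract_payload(html), assets_inlined=True
    )
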