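"""Deterministic SVG rendering of gene landscapes and clone lollipop panels.

The drawing is plain hand-assembled SVG text so that identical inputs yield
byte-identical files (no timestamps, no library-version metadata).  Elements
carry CSS classes (``cpg-tick``, ``exon``, ``island``, ``shore``,
``assay-region``, ``lollipop-*``) so tests and downstream tooling can count
features directly.
"""

from __future__ import annotations

from .landscape import GeneLandscape, to_display_coordinates

_STYLE = """
  .backbone { stroke: #444; stroke-width: 1; }
  .cpg-tick { stroke: #1a1a1a; stroke-width: 0.6; }
  .exon { fill: #ffffff; stroke: #222; stroke-width: 1; }
  .exon-label { font: 9px sans-serif; text-anchor: middle; }
  .island { fill: #7fb2d9; fill-opacity: 0.45; }
  .shore { fill: #f2c26b; fill-opacity: 0.45; }
  .assay-region { stroke: #000; stroke-width: 3; }
  .assay-label { font: 10px serif; text-anchor: middle; }
  .axis-label { font: 9px sans-serif; text-anchor: middle; }
  .lollipop-meth { fill: #000; stroke: #000; }
  .lollipop-unmeth { fill: #fff; stroke: #000; }
  .lollipop-absent { stroke: #000; stroke-width: 0.8; }
"""


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def render_landscape(
    landscape: GeneLandscape,
    output_path: str,
    width: float = 900.0,
    clone_calls: list[list[str]] | None = None,
    clone_cpg_offsets: list[int] | None = None,
) -> str:
    """Write a Fig-1-style locus diagram as SVG and return the markup.

    Tracks from top to bottom: island/shore shading, the gene backbone with
    exon rectangles and numbers, CpG tick marks, assay-region bars, and an
    optional clone lollipop panel (filled = methylated, open = unmethylated,
    cross = CpG absent).
    """
    gm = landscape.gene_model
    L = gm.locus_length
    margin = 40.0
    scale = (width - 2 * margin) / max(L, 1)

    def x(off: int) -> float:
        return margin + off * scale

    y_backbone = 90.0
    tick_top, tick_bot = 55.0, 75.0
    exon_h = 14.0
    bar_y = 112.0
    body: list[str] = []

    for isl in landscape.islands:
        body.append(
            f'<rect class="island" x="{_fmt(x(isl.start))}" y="40" '
            f'width="{_fmt((isl.end - isl.start) * scale)}" height="60"/>'
        )
    for sh in landscape.shores:
        body.append(
            f'<rect class="shore" x="{_fmt(x(sh.start))}" y="40" '
            f'width="{_fmt((sh.end - sh.start) * scale)}" height="60"/>'
        )

    body.append(
        f'<line class="backbone" x1="{_fmt(x(0))}" y1="{_fmt(y_backbone)}" '
        f'x2="{_fmt(x(L))}" y2="{_fmt(y_backbone)}"/>'
    )
    for p in landscape.cpg_map.positions:
        body.append(
            f'<line class="cpg-tick" x1="{_fmt(x(p))}" y1="{_fmt(tick_top)}" '
            f'x2="{_fmt(x(p))}" y2="{_fmt(tick_bot)}"/>'
        )
    for i, (s, e) in enumerate(gm.exon_offsets(), start=1):
        body.append(
            f'<rect class="exon" x="{_fmt(x(s))}" y="{_fmt(y_backbone - exon_h / 2)}" '
            f'width="{_fmt(max((e - s) * scale, 1.0))}" height="{_fmt(exon_h)}"/>'
        )
        body.append(
            f'<text class="exon-label" x="{_fmt(x(s) + (e - s) * scale / 2)}" '
            f'y="{_fmt(y_backbone - exon_h / 2 - 3)}">{i}</text>'
        )
    for r in landscape.assay_regions:
        body.append(
            f'<line class="assay-region" x1="{_fmt(x(r.start))}" y1="{_fmt(bar_y)}" '
            f'x2="{_fmt(x(r.end))}" y2="{_fmt(bar_y)}"/>'
        )
        if r.label:
            body.append(
                f'<text class="assay-label" x="{_fmt((x(r.start) + x(r.end)) / 2)}" '
                f'y="{_fmt(bar_y + 12)}">{r.label}</text>'
            )

    left = to_display_coordinates(0, gm)
    right = to_display_coordinates(L - 1, gm)
    body.append(
        f'<text class="axis-label" x="{_fmt(x(0))}" y="130">({left:,})</text>'
    )
    body.append(
        f'<text class="axis-label" x="{_fmt(x(L - 1))}" y="130">({right:,})</text>'
    )

    height = 140.0
    if clone_calls:
        offsets = clone_cpg_offsets or list(landscape.cpg_map.positions)
        y0 = 150.0
        row_h, r_px = 9.0, 3.0
        for row, calls in enumerate(clone_calls):
            cy = y0 + row * row_h
            for call, off in zip(calls, offsets):
                cx = x(off)
                if call == "methylated":
                    body.append(
                        f'<circle class="lollipop-meth" cx="{_fmt(cx)}" '
                        f'cy="{_fmt(cy)}" r="{_fmt(r_px)}"/>'
                    )
                elif call == "unmethylated":
                    body.append(
                        f'<circle class="lollipop-unmeth" cx="{_fmt(cx)}" '
                        f'cy="{_fmt(cy)}" r="{_fmt(r_px)}"/>'
                    )
                else:  # absent
                    body.append(
                        f'<g class="lollipop-absent">'
                        f'<line x1="{_fmt(cx - r_px)}" y1="{_fmt(cy - r_px)}" '
                        f'x2="{_fmt(cx + r_px)}" y2="{_fmt(cy + r_px)}"/>'
                        f'<line x1="{_fmt(cx - r_px)}" y1="{_fmt(cy + r_px)}" '
                        f'x2="{_fmt(cx + r_px)}" y2="{_fmt(cy - r_px)}"/></g>'
                    )
        height = y0 + len(clone_calls) * row_h + 10.0

    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(width)}" '
        f'height="{_fmt(height)}" viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
        f"<style>{_STYLE}</style>\n"
        f'<title>{gm.gene_id} CpG landscape</title>\n'
        + "\n".join(body)
        + "\n</svg>\n"
    )
    with open(output_path, "w") as fh:
        fh.write(svg)
    return svg
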