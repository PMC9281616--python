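"""Thin interactive web front end (optional; needs dash + dash-cytoscape).

Every control mutates exactly one field of the FilterSpec, LayoutParams or
StyleConfig and re-enters :func:`compositegraph.view_state.update_state`;
no computation lives in this layer.  The engine is fully usable without it.
"""

from __future__ import annotations

import base64
import io
from dataclasses import replace

import dash
import dash_cytoscape as cyto
from dash import Input, Output, State, dcc, html

from .edge_table import EdgeTable, EdgeTableError, read_edge_table
from .filtering import FilterSpec
from .layout import LayoutParams
from .view_state import initialize_state, update_state


def create_app(table: EdgeTable) -> "dash.Dash":
    state = initialize_state(table)
    holder = {"state": state}

    frame = table.frame
    vmin, vmax = float(frame["edge_value"].min()), float(frame["edge_value"].max())
    bounds = state.view.bounds
    target_names = sorted(table.target_names)
    source_names = sorted(table.source_names)
    type_labels = sorted(table.types)
    n_sources = len(table.source_ids)

    app = dash.Dash("compositegraph")
    app.layout = html.Div([
        html.H3("compositegraph"),
        dcc.Upload(id="upload", children=html.Button("Upload CSV")),
        html.Div(id="upload-status"),
        html.Label("Edge value range"),
        dcc.RangeSlider(id="edge-range", min=vmin, max=vmax,
                        value=[vmin, vmax], step=(vmax - vmin) / 100 or 0.01),
        html.Label("Combined value range"),
        dcc.RangeSlider(id="combined-range", min=bounds.lo, max=bounds.hi,
                        value=[bounds.lo, bounds.hi],
                        step=(bounds.hi - bounds.lo) / 100 or 0.01),
        html.Label("Max node count"),
        dcc.Slider(id="max-nodes", min=1, max=n_sources, value=n_sources, step=1),
        html.Label("Targets"),
        dcc.Dropdown(id="targets", options=target_names, multi=True),
        html.Label("Sources"),
        dcc.Dropdown(id="sources", options=source_names, multi=True),
        html.Label("Types"),
        dcc.Dropdown(id="types", options=type_labels, multi=True),
        html.Label("Target spread"),
        dcc.Slider(id="target-spread", min=0.1, max=5.0, value=1.0, step=0.1),
        html.Label("Source spread"),
        dcc.Slider(id="source-spread", min=0.1, max=5.0, value=1.0, step=0.1),
        html.Label("Simulation iterations"),
        dcc.Slider(id="iterations", min=0, max=100, value=15, step=1),
        html.Button("Re-simulate", id="resimulate", n_clicks=0),
        html.Button("Randomize colors", id="recolor", n_clicks=0),
        cyto.Cytoscape(id="graph", elements=state.elements(),
                       layout={"name": "preset"},
                       style={"width": "100%", "height": "700px"}),
    ])

    @app.callback(
        Output("graph", "elements"),
        Output("upload-status", "children"),
        Input("edge-range", "value"),
        Input("combined-range", "value"),
        Input("max-nodes", "value"),
        Input("targets", "value"),
        Input("sources", "value"),
        Input("types", "value"),
        Input("target-spread", "value"),
        Input("source-spread", "value"),
        Input("iterations", "value"),
        Input("resimulate", "n_clicks"),
        Input("recolor", "n_clicks"),
        Input("upload", "contents"),
    )
    def refresh(edge_range, combined_range, max_nodes, targets, sources, types,
                target_spread, source_spread, iterations, n_resim, n_recolor,
                upload_contents):
        current = holder["state"]
        status = ""
        trigger = dash.ctx.triggered_id

        if trigger == "upload" and upload_contents:
            try:
                _, payload = upload_contents.split(",", 1)
                text = base64.b64decode(payload).decode("utf-8")
                new_table = read_edge_table(io.StringIO(text))
                holder["state"] = initialize_state(
                    new_table, layout_params=current.layout_params,
                    style=current.style, aggregator=current.aggregator)
                return holder["state"].elements(), "upload OK"
            except (EdgeTableError, ValueError) as exc:
                # invalid upload: keep the prior graph intact
                return current.elements(), f"upload rejected: {exc}"

        spec = FilterSpec(
            edge_value_range=tuple(edge_range) if edge_range else None,
            combined_range=tuple(combined_range) if combined_range else None,
            max_nodes=int(max_nodes) if max_nodes else None,
            include_targets=frozenset(targets) if targets else None,
            include_source_names=frozenset(sources) if sources else None,
            include_types=frozenset(types) if types else None,
        )
        params = replace(
            current.layout_params,
            target_spread=float(target_spread),
            source_spread=float(source_spread),
            refine_iterations=int(iterations),
        )
        style = replace(current.style, color_seed=int(n_recolor or 0))
        holder["state"] = update_state(
            current, spec, layout_params=params, style=style,
            resimulate=(trigger == "resimulate"),
        )
        return holder["state"].elements(), status

    return app
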