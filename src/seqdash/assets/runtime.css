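.seqdash-widget {
  font-family: "Helvetica Neue", Arial, sans-serif;
  font-size: 13px;
  color: #222;
  max-width: 820px;
}
.seqdash-row { display: flex; gap: 16px; align-items: flex-start; }
.seqdash-panel { flex: 0 0 auto; }
.seqdash-controls { margin: 6px 0; display: flex; flex-wrap: wrap; gap: 6px; }
.seqdash-controls button,
.seqdash-controls select,
.seqdash-controls input {
  font-size: 12px;
  padding: 2px 6px;
}
.seqdash-plot { background: #fff; border: 1px solid #ddd; }
.seqdash-axis { stroke: #444; stroke-width: 1; }
.seqdash-axis-label { font-size: 11px; fill: #444; }
.seqdash-point { cursor: pointer; opacity: 0.85; }
.seqdash-point:hover { opacity: 1; }
.seqdash-strip {
  margin: 6px 0;
  padding: 4px 6px;
  background: #f4f4f4;
  border: 1px solid #e0e0e0;
  font-family: monospace;
}
.seqdash-table-wrap { max-height: 260px; overflow: auto; margin-top: 6px; }
.seqdash-table { border-collapse: collapse; width: 100%; }
.seqdash-table th,
.seqdash-table td {
  border: 1px solid #e0e0e0;
  padding: 2px 6px;
  text-align: left;
  white-space: nowrap;
}
.seqdash-table th { position: sticky; top: 0; background: #fafafa; }
.seqdash-table tr:hover { background: #eef5fb; }
.seqdash-selected-row { background: #fde9c8; }
.seqdash-hint { color: #888; padding: 12px; }
.seqdash-search { min-width: 180px; }
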