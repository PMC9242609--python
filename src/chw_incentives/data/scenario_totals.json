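{
  "comment": "Published grand totals (INR per month, catchment 1000). Per-incentive inputs behind them are not public, so they enter as fixtures and only the arithmetic identities on them are verified.",
  "pp": 5867,
  "pa": 3000,
  "aa": 1325,
  "observed_total": 2580
}
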