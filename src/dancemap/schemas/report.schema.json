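{
 "description": "Schema of ``report.json``; the JSON schema ships with the package\n(``dancemap/schemas/report.schema.json``).",
 "properties": {
  "calibration_estimator": {
   "title": "Calibration Estimator",
   "type": "string"
  },
  "calibration_n": {
   "anyOf": [
    {
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Calibration N"
  },
  "calibration_v": {
   "title": "Calibration V",
   "type": "number"
  },
  "calibration_v_rounded": {
   "title": "Calibration V Rounded",
   "type": "integer"
  },
  "circle_center_lat": {
   "title": "Circle Center Lat",
   "type": "number"
  },
  "circle_center_lon": {
   "title": "Circle Center Lon",
   "type": "number"
  },
  "circle_diameter_m": {
   "title": "Circle Diameter M",
   "type": "number"
  },
  "dance_rate_per_min": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Dance Rate Per Min"
  },
  "dance_rate_rounded": {
   "anyOf": [
    {
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Dance Rate Rounded"
  },
  "n_dances": {
   "title": "N Dances",
   "type": "integer"
  },
  "n_night_phases": {
   "title": "N Night Phases",
   "type": "integer"
  },
  "n_phases": {
   "title": "N Phases",
   "type": "integer"
  },
  "nyquist_adequate": {
   "title": "Nyquist Adequate",
   "type": "boolean"
  },
  "nyquist_margin": {
   "title": "Nyquist Margin",
   "type": "number"
  },
  "peak_lat": {
   "title": "Peak Lat",
   "type": "number"
  },
  "peak_lon": {
   "title": "Peak Lon",
   "type": "number"
  },
  "ring_spacing_m": {
   "title": "Ring Spacing M",
   "type": "number"
  },
  "ring_spacing_rounded_m": {
   "title": "Ring Spacing Rounded M",
   "type": "integer"
  },
  "sampling_sufficient": {
   "title": "Sampling Sufficient",
   "type": "boolean"
  },
  "sector_width_deg": {
   "title": "Sector Width Deg",
   "type": "number"
  },
  "session_span_min": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Session Span Min"
  },
  "waggle_accuracy_m": {
   "title": "Waggle Accuracy M",
   "type": "number"
  },
  "waggle_accuracy_rounded_m": {
   "title": "Waggle Accuracy Rounded M",
   "type": "integer"
  }
 },
 "required": [
  "n_phases",
  "n_dances",
  "calibration_v",
  "calibration_v_rounded",
  "calibration_estimator",
  "peak_lat",
  "peak_lon",
  "circle_center_lat",
  "circle_center_lon",
  "circle_diameter_m",
  "sector_width_deg",
  "ring_spacing_m",
  "ring_spacing_rounded_m",
  "waggle_accuracy_m",
  "waggle_accuracy_rounded_m",
  "nyquist_margin",
  "nyquist_adequate",
  "sampling_sufficient",
  "n_night_phases"
 ],
 "title": "SearchAreaReport",
 "type": "object"
}
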