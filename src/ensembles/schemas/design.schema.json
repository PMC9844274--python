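{
 "$defs": {
  "SpecModel": {
   "properties": {
    "task": {
     "title": "Task",
     "type": "string"
    },
    "mean_length": {
     "title": "Mean Length",
     "type": "number"
    },
    "sd_length": {
     "title": "Sd Length",
     "type": "number"
    },
    "mean_orientation": {
     "title": "Mean Orientation",
     "type": "number"
    },
    "sd_orientation": {
     "title": "Sd Orientation",
     "type": "number"
    },
    "repetition": {
     "maximum": 2,
     "minimum": 1,
     "title": "Repetition",
     "type": "integer"
    }
   },
   "required": [
    "task",
    "mean_length",
    "sd_length",
    "mean_orientation",
    "sd_orientation",
    "repetition"
   ],
   "title": "SpecModel",
   "type": "object"
  },
  "TrialModel": {
   "properties": {
    "trial_index": {
     "minimum": 0,
     "title": "Trial Index",
     "type": "integer"
    },
    "spec": {
     "$ref": "#/$defs/SpecModel"
    },
    "lengths": {
     "items": {
      "type": "number"
     },
     "maxItems": 12,
     "minItems": 12,
     "title": "Lengths",
     "type": "array"
    },
    "orientations": {
     "items": {
      "type": "number"
     },
     "maxItems": 12,
     "minItems": 12,
     "title": "Orientations",
     "type": "array"
    },
    "layout": {
     "additionalProperties": true,
     "title": "Layout",
     "type": "object"
    }
   },
   "required": [
    "trial_index",
    "spec",
    "lengths",
    "orientations",
    "layout"
   ],
   "title": "TrialModel",
   "type": "object"
  }
 },
 "properties": {
  "provenance": {
   "additionalProperties": true,
   "title": "Provenance",
   "type": "object"
  },
  "display": {
   "additionalProperties": true,
   "title": "Display",
   "type": "object"
  },
  "tasks": {
   "additionalProperties": {
    "items": {
     "$ref": "#/$defs/TrialModel"
    },
    "type": "array"
   },
   "title": "Tasks",
   "type": "object"
  }
 },
 "required": [
  "provenance",
  "display",
  "tasks"
 ],
 "title": "DesignDocument",
 "type": "object"
}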