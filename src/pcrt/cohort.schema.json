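{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "pcrt cohort",
 "type": "object",
 "required": [
  "respondents"
 ],
 "properties": {
  "respondents": {
   "type": "array",
   "items": {
    "$defs": {
     "CancerEvent": {
      "description": "One cancer diagnosis reported for a person.\n\n``other`` carries an optional free-text label and scores zero under\nthe default point table.",
      "properties": {
       "cancer_type": {
        "$ref": "#/$defs/CancerType"
       },
       "dx_at_or_before_50": {
        "$ref": "#/$defs/TriState",
        "default": "unknown"
       },
       "label": {
        "anyOf": [
         {
          "type": "string"
         },
         {
          "type": "null"
         }
        ],
        "default": null,
        "title": "Label"
       }
      },
      "required": [
       "cancer_type"
      ],
      "title": "CancerEvent",
      "type": "object"
     },
     "CancerType": {
      "enum": [
       "pancreatic",
       "breast",
       "ovarian",
       "colorectal",
       "prostate",
       "thyroid",
       "melanoma",
       "other"
      ],
      "title": "CancerType",
      "type": "string"
     },
     "Ethnicity": {
      "enum": [
       "White",
       "African American",
       "Asian",
       "Other"
      ],
      "title": "Ethnicity",
      "type": "string"
     },
     "NODResponses": {
      "description": "New-onset-diabetes questionnaire section.\n\n``section_completed`` is False when the section was never answered;\nsuch respondents fall outside the NOD funnel denominator entirely.\nWeights are in pounds; ``None`` means the respondent could not recall.",
      "properties": {
       "section_completed": {
        "default": true,
        "title": "Section Completed",
        "type": "boolean"
       },
       "weight_current_lb": {
        "anyOf": [
         {
          "type": "number"
         },
         {
          "type": "null"
         }
        ],
        "default": null,
        "title": "Weight Current Lb"
       },
       "weight_one_year_ago_lb": {
        "anyOf": [
         {
          "type": "number"
         },
         {
          "type": "null"
         }
        ],
        "default": null,
        "title": "Weight One Year Ago Lb"
       },
       "glucose_elevated": {
        "$ref": "#/$defs/TriState",
        "default": "unknown"
       },
       "diabetes_or_glucose_intolerance": {
        "default": false,
        "title": "Diabetes Or Glucose Intolerance",
        "type": "boolean"
       },
       "glycemic_change_around_age_50_or_later": {
        "$ref": "#/$defs/TriState",
        "default": "unknown"
       }
      },
      "title": "NODResponses",
      "type": "object"
     },
     "PersonHistory": {
      "description": "Cancer events for one person in the respondent's first-degree circle.\n\n``relation_index`` distinguishes multiple siblings (1-based); it is 0\nfor self, mother and father.",
      "properties": {
       "relation": {
        "$ref": "#/$defs/Relation"
       },
       "relation_index": {
        "default": 0,
        "title": "Relation Index",
        "type": "integer"
       },
       "events": {
        "default": [],
        "items": {
         "$ref": "#/$defs/CancerEvent"
        },
        "title": "Events",
        "type": "array"
       }
      },
      "required": [
       "relation"
      ],
      "title": "PersonHistory",
      "type": "object"
     },
     "Relation": {
      "enum": [
       "self",
       "mother",
       "father",
       "sibling"
      ],
      "title": "Relation",
      "type": "string"
     },
     "Sex": {
      "enum": [
       "female",
       "male",
       "other"
      ],
      "title": "Sex",
      "type": "string"
     },
     "TriState": {
      "description": "Yes / no / unknown answer to a questionnaire item.",
      "enum": [
       "yes",
       "no",
       "unknown"
      ],
      "title": "TriState",
      "type": "string"
     }
    },
    "description": "One respondent's full questionnaire record.",
    "properties": {
     "patient_id": {
      "title": "Patient Id",
      "type": "string"
     },
     "age": {
      "title": "Age",
      "type": "integer"
     },
     "sex": {
      "$ref": "#/$defs/Sex"
     },
     "ethnicity": {
      "$ref": "#/$defs/Ethnicity",
      "default": "White"
     },
     "ashkenazi_mother": {
      "$ref": "#/$defs/TriState",
      "default": "unknown"
     },
     "ashkenazi_father": {
      "$ref": "#/$defs/TriState",
      "default": "unknown"
     },
     "current_smoker": {
      "default": false,
      "title": "Current Smoker",
      "type": "boolean"
     },
     "prior_genetic_testing": {
      "default": false,
      "title": "Prior Genetic Testing",
      "type": "boolean"
     },
     "preexisting_pancreatic_cancer": {
      "default": false,
      "title": "Preexisting Pancreatic Cancer",
      "type": "boolean"
     },
     "persons": {
      "items": {
       "$ref": "#/$defs/PersonHistory"
      },
      "title": "Persons",
      "type": "array"
     },
     "nod": {
      "$ref": "#/$defs/NODResponses"
     }
    },
    "required": [
     "patient_id",
     "age",
     "sex"
    ],
    "title": "PatientResponse",
    "type": "object"
   }
  }
 }
}
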