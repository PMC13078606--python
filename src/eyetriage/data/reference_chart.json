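{
  "name": "reference acuity chart (synthetic demonstrative stand-in)",
  "comment": "Chart rows pair symptom-feature patterns with an urgency grade (A: same day, B: within 24 h, C: 48-72 h, D: within the week) and a service route, following the urgency categories of published emergency eye care guidance. Rows whose source material is ambiguous were editor-filled from those categories; this config is a synthetic stand-in for evaluation of the software, not a clinical instrument.",
  "default": {"urgency": "C", "service": "community_urgent_eye_service"},
  "rules": [
    {"label": "chemical injury", "features": ["chemical_injury"], "urgency": "A", "service": "ED"},
    {"label": "penetrating / high-velocity injury", "features": ["penetrating_injury"], "urgency": "A", "service": "ED"},
    {"label": "sudden painless loss of vision", "features": ["sudden_vision_loss"], "urgency": "A", "service": "ED"},
    {"label": "visual disturbance with stroke symptoms", "features": ["stroke_symptoms"], "urgency": "A", "service": "ED"},
    {"label": "blunt trauma", "features": ["blunt_injury"], "urgency": "B", "service": "EEC"},
    {"label": "injury with reduced vision", "features": ["injury_vision_change"], "urgency": "B", "service": "EEC"},
    {"label": "surface foreign body / abrasion", "features": ["surface_injury"], "urgency": "C", "service": "community_urgent_eye_service"},
    {"label": "new flashes or floaters", "features": ["flashes_floaters"], "urgency": "B", "service": "hospital_urgent_eye_service"},
    {"label": "new double vision", "features": ["diplopia"], "urgency": "B", "service": "EEC"},
    {"label": "gradual blurring", "features": ["gradual_blur"], "urgency": "C", "service": "community_urgent_eye_service"},
    {"label": "gradual blurring, both eyes", "features": ["gradual_blur", "both_eyes"], "urgency": "D", "service": "private_optometry"},
    {"label": "severe pain with systemic upset", "features": ["severe_pain"], "urgency": "A", "service": "EEC"},
    {"label": "red eye with reduced vision", "features": ["red_vision_affected"], "urgency": "B", "service": "EEC"},
    {"label": "red eye with photophobia", "features": ["photophobia"], "urgency": "B", "service": "hospital_urgent_eye_service"},
    {"label": "contact lens wearer with painful red eye", "features": ["moderate_pain", "contact_lens"], "urgency": "B", "service": "EEC"},
    {"label": "moderate pain or grittiness", "features": ["moderate_pain"], "urgency": "C", "service": "community_urgent_eye_service"},
    {"label": "painless red eye", "features": ["no_pain"], "urgency": "D", "service": "private_optometry"},
    {"label": "lid swelling with spreading redness", "features": ["lid_swelling", "periorbital_redness"], "urgency": "A", "service": "ED"},
    {"label": "painful lid swelling", "features": ["lid_swelling"], "urgency": "C", "service": "community_urgent_eye_service"},
    {"label": "lid lump", "features": ["lid_lump"], "urgency": "D", "service": "private_optometry"},
    {"label": "blepharitis / crusting", "features": ["lid_crusting"], "urgency": "D", "service": "pharmacy"},
    {"label": "new lid droop", "features": ["lid_droop"], "urgency": "B", "service": "EEC"},
    {"label": "recent intraocular surgery or injection", "features": ["recent_surgery"], "urgency": "B", "service": "EEC"}
  ]
}
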