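{
  "name": "reference symptom questionnaire (synthetic demonstrative stand-in)",
  "comment": "Demonstrative questionnaire authored for this package. The entry question reproduces the four-way presenting-concern filter; the branches cover the symptom rows of the companion reference chart. The deployed tool's proprietary question set is not public; this config is a synthetic stand-in, not a clinical instrument.",
  "entry": "q_entry",
  "max_questions": 25,
  "questions": [
    {
      "id": "q_entry",
      "text": "Which of these best describes your main eye problem today?",
      "category": "symptomatology",
      "options": [
        {"id": "red_painful", "label": "Red or painful eye", "concern": "red_or_painful_eye", "next": "q_red_pain"},
        {"id": "vision", "label": "Painless visual disturbance", "concern": "painless_visual_disturbance", "next": "q_vis_onset"},
        {"id": "injury", "label": "Eye injury", "concern": "eye_injury", "next": "q_inj_type"},
        {"id": "eyelid", "label": "Eyelid problem", "concern": "eyelid_problem", "next": "q_lid_type"}
      ]
    },

    {
      "id": "q_inj_type",
      "text": "What kind of injury was it?",
      "category": "symptomatology",
      "options": [
        {"id": "chemical", "label": "Chemical or liquid splashed into the eye", "fast_track": true, "feature_tags": ["chemical_injury"]},
        {"id": "penetrating", "label": "Something sharp or fast-moving hit or entered the eye", "fast_track": true, "feature_tags": ["penetrating_injury"]},
        {"id": "blunt", "label": "A blunt knock or blow to the eye", "feature_tags": ["blunt_injury"], "next": "q_inj_vision"},
        {"id": "surface", "label": "A scratch, or something feels stuck on the surface", "feature_tags": ["surface_injury"], "next": "q_inj_vision"}
      ]
    },
    {
      "id": "q_inj_vision",
      "text": "Has your vision changed since the injury?",
      "category": "symptomatology",
      "options": [
        {"id": "yes", "label": "Yes, it is worse", "feature_tags": ["injury_vision_change"], "next": "q_hist_surgery"},
        {"id": "no", "label": "No, it is unchanged", "next": "q_hist_surgery"}
      ]
    },

    {
      "id": "q_vis_onset",
      "text": "How did the change in your vision start?",
      "category": "symptomatology",
      "options": [
        {"id": "sudden_loss", "label": "Sudden loss of all or part of my vision", "fast_track": true, "feature_tags": ["sudden_vision_loss"]},
        {"id": "flashes", "label": "New floaters or flashing lights", "feature_tags": ["flashes_floaters"], "next": "q_vis_stroke"},
        {"id": "gradual", "label": "Gradual blurring over days", "feature_tags": ["gradual_blur"], "next": "q_vis_stroke"},
        {"id": "double", "label": "Seeing double", "feature_tags": ["diplopia"], "next": "q_vis_stroke"}
      ]
    },
    {
      "id": "q_vis_stroke",
      "text": "Do you also have new weakness of your face or arm, or difficulty speaking?",
      "category": "symptomatology",
      "options": [
        {"id": "yes", "label": "Yes", "fast_track": true, "feature_tags": ["stroke_symptoms"]},
        {"id": "no", "label": "No", "next": "q_vis_side"}
      ]
    },
    {
      "id": "q_vis_side",
      "text": "Is the problem in one eye or both?",
      "category": "symptomatology",
      "options": [
        {"id": "one", "label": "One eye", "feature_tags": ["one_eye"], "next": "q_hist_surgery"},
        {"id": "both", "label": "Both eyes", "feature_tags": ["both_eyes"], "next": "q_hist_surgery"}
      ]
    },

    {
      "id": "q_red_pain",
      "text": "How painful is the eye?",
      "category": "symptomatology",
      "options": [
        {"id": "severe", "label": "Severe pain, perhaps with headache or feeling sick", "feature_tags": ["severe_pain"], "next": "q_red_vision"},
        {"id": "moderate", "label": "Moderate pain or a gritty, burning feeling", "feature_tags": ["moderate_pain"], "next": "q_red_vision"},
        {"id": "none", "label": "No pain, the eye is just red", "feature_tags": ["no_pain"], "next": "q_red_vision"}
      ]
    },
    {
      "id": "q_red_vision",
      "text": "Is the vision in that eye affected?",
      "category": "symptomatology",
      "options": [
        {"id": "yes", "label": "Yes", "feature_tags": ["red_vision_affected"], "next": "q_red_lens"},
        {"id": "no", "label": "No", "next": "q_red_lens"}
      ]
    },
    {
      "id": "q_red_lens",
      "text": "Do you wear contact lenses?",
      "category": "ophthalmic_history",
      "options": [
        {"id": "yes", "label": "Yes", "feature_tags": ["contact_lens"], "next": "q_red_photo"},
        {"id": "no", "label": "No", "next": "q_red_photo"}
      ]
    },
    {
      "id": "q_red_photo",
      "text": "Is the eye unusually sensitive to light?",
      "category": "symptomatology",
      "options": [
        {"id": "yes", "label": "Yes", "feature_tags": ["photophobia"], "next": "q_hist_surgery"},
        {"id": "no", "label": "No", "next": "q_hist_surgery"}
      ]
    },

    {
      "id": "q_lid_type",
      "text": "What is the problem with the eyelid?",
      "category": "symptomatology",
      "options": [
        {"id": "swelling", "label": "Painful swelling of the lid", "feature_tags": ["lid_swelling"], "next": "q_lid_spread"},
        {"id": "lump", "label": "A lump that is not very painful", "feature_tags": ["lid_lump"], "next": "q_lid_spread"},
        {"id": "crusting", "label": "Itchy, crusty or flaky lid edges", "feature_tags": ["lid_crusting"], "next": "q_lid_spread"},
        {"id": "droop", "label": "The lid has started to droop", "feature_tags": ["lid_droop"], "next": "q_lid_spread"}
      ]
    },
    {
      "id": "q_lid_spread",
      "text": "Is the skin around the eye red, hot and spreading?",
      "category": "symptomatology",
      "options": [
        {"id": "yes", "label": "Yes", "feature_tags": ["periorbital_redness"], "next": "q_hist_surgery"},
        {"id": "no", "label": "No", "next": "q_hist_surgery"}
      ]
    },

    {
      "id": "q_hist_surgery",
      "text": "Have you had eye surgery or an eye injection in the last month?",
      "category": "ophthalmic_history",
      "options": [
        {"id": "yes", "label": "Yes", "feature_tags": ["recent_surgery"], "next": "q_hist_condition"},
        {"id": "no", "label": "No", "next": "q_hist_condition"}
      ]
    },
    {
      "id": "q_hist_condition",
      "text": "Do you have an existing eye condition?",
      "category": "ophthalmic_history",
      "options": [
        {"id": "glaucoma", "label": "Glaucoma", "feature_tags": ["history_glaucoma"], "next": "q_medication"},
        {"id": "amd", "label": "Macular degeneration", "feature_tags": ["history_amd"], "next": "q_medication"},
        {"id": "other", "label": "Another eye condition", "feature_tags": ["history_other"], "next": "q_medication"},
        {"id": "none", "label": "No", "next": "q_medication"}
      ]
    },
    {
      "id": "q_medication",
      "text": "Do you take any of these medicines?",
      "category": "medication",
      "allows_free_text": true,
      "options": [
        {"id": "anticoagulant", "label": "Blood thinners (e.g. warfarin, apixaban)", "feature_tags": ["anticoagulant"]},
        {"id": "immunosuppressant", "label": "Medicines that suppress the immune system", "feature_tags": ["immunosuppressed"]},
        {"id": "none", "label": "Neither of these"}
      ]
    }
  ]
}
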