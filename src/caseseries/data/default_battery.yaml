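# Default 22-test visual-perception battery schema.
#
# Each entry declares the test's cognitive domain, its measures with score
# direction, and whether the test enters the domain composite scores
# (in_composite).  Domains: low_level (low/intermediate vision), word,
# object, face.  RT measures are lower_is_better; accuracy-type measures
# are higher_is_better.
tests:
  # -- low / intermediate level vision ------------------------------------
  - test_id: rvf_deficit
    domain: low_level
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: visual_acuity
    domain: low_level
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: lpost
    domain: low_level
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}

  # -- words ---------------------------------------------------------------
  - test_id: delayed_matching_words
    domain: word
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: surprise_recognition_words
    domain: word
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: lexical_decision
    domain: word
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: word_reading
    domain: word
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: regular_word_reading
    domain: word
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: exception_word_reading
    domain: word
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: nonword_reading
    domain: word
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: text_reading
    domain: word
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}

  # -- objects -------------------------------------------------------------
  - test_id: delayed_matching_objects
    domain: object
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: surprise_recognition_objects
    domain: object
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: object_decision
    domain: object
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: picture_naming
    domain: object
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: house_memory
    domain: object
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: object_categorisation
    domain: object
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}

  # -- faces ---------------------------------------------------------------
  - test_id: delayed_matching_faces
    domain: face
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: surprise_recognition_faces
    domain: face
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: face_familiarity
    domain: face
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
      - {measure_id: rt, direction: lower_is_better}
  - test_id: famous_face_naming
    domain: face
    in_composite: true
    measures:
      - {measure_id: acc, direction: higher_is_better}
  - test_id: face_memory
    domain: face
    in_composite: false
    measures:
      - {measure_id: acc, direction: higher_is_better}
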