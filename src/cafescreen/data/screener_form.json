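[
 {
  "item_id": "orientation_full_name",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_date_day",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_date_month",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_date_year",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_day_of_week",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_season",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_current_age",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_phone_number",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_current_location",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "orientation_country",
  "domain": "orientation",
  "max_points": 1
 },
 {
  "item_id": "counting_backwards",
  "domain": "attention_working_memory",
  "max_points": 2
 },
 {
  "item_id": "serial_sevens",
  "domain": "attention_working_memory",
  "max_points": 5
 },
 {
  "item_id": "backward_digit_span",
  "domain": "attention_working_memory",
  "max_points": 1
 },
 {
  "item_id": "object_naming",
  "domain": "language",
  "max_points": 2
 },
 {
  "item_id": "concept_formation",
  "domain": "language",
  "max_points": 1
 },
 {
  "item_id": "phrase_repetition",
  "domain": "language",
  "max_points": 1
 },
 {
  "item_id": "comprehension_instructions",
  "domain": "language",
  "max_points": 1
 },
 {
  "item_id": "word_list_immediate_1_2",
  "domain": "memory_immediate",
  "max_points": 2
 },
 {
  "item_id": "word_list_immediate_3_4",
  "domain": "memory_immediate",
  "max_points": 2
 },
 {
  "item_id": "word_list_immediate_5_6",
  "domain": "memory_immediate",
  "max_points": 2
 },
 {
  "item_id": "word_list_immediate_7_8",
  "domain": "memory_immediate",
  "max_points": 2
 },
 {
  "item_id": "word_list_immediate_9_10",
  "domain": "memory_immediate",
  "max_points": 2
 },
 {
  "item_id": "word_list_delayed",
  "domain": "memory_delayed",
  "max_points": 6
 }
]
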