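[
 {
  "item_id": "sausages_and_eggs",
  "display_name": "sausages and eggs",
  "category": "savoury_food",
  "is_filler": false,
  "recognition_meta": {
   "overall": 1.0,
   "younger": 1.0,
   "older": 1.0
  }
 },
 {
  "item_id": "smoked_salmon_poached_egg_toast",
  "display_name": "smoked salmon and poached egg on toast",
  "category": "savoury_food",
  "is_filler": true
 },
 {
  "item_id": "bacon_and_egg_roll",
  "display_name": "bacon and egg roll",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "avocado_toast",
  "display_name": "avocado toast",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "ham_cheese_toastie",
  "display_name": "ham and cheese toastie",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "mushroom_omelette",
  "display_name": "mushroom omelette",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "eggs_benedict",
  "display_name": "eggs benedict",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "big_breakfast",
  "display_name": "big breakfast",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "chicken_caesar_salad",
  "display_name": "chicken caesar salad",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "pumpkin_soup",
  "display_name": "pumpkin soup",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "beef_burger",
  "display_name": "beef burger",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "club_sandwich",
  "display_name": "club sandwich",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "quiche_lorraine",
  "display_name": "quiche lorraine",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "sausage_roll",
  "display_name": "sausage roll",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "meat_pie",
  "display_name": "meat pie",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "fish_and_chips",
  "display_name": "fish and chips",
  "category": "savoury_food",
  "is_filler": false
 },
 {
  "item_id": "waffle",
  "display_name": "waffle",
  "category": "sweet_food",
  "is_filler": false,
  "recognition_meta": {
   "overall": 1.0,
   "younger": 1.0,
   "older": 1.0
  }
 },
 {
  "item_id": "croissant",
  "display_name": "croissant",
  "category": "sweet_food",
  "is_filler": false,
  "recognition_meta": {
   "overall": 1.0,
   "younger": 1.0,
   "older": 1.0
  }
 },
 {
  "item_id": "cereal",
  "display_name": "cereal",
  "category": "sweet_food",
  "is_filler": false,
  "recognition_meta": {
   "younger": 1.0,
   "older": 0.8
  }
 },
 {
  "item_id": "smoothie_bowl",
  "display_name": "smoothie bowl",
  "category": "sweet_food",
  "is_filler": true,
  "recognition_meta": {
   "younger": 0.729,
   "older": 0.344
  }
 },
 {
  "item_id": "pancakes",
  "display_name": "pancakes",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "banana_bread",
  "display_name": "banana bread",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "blueberry_muffin",
  "display_name": "blueberry muffin",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "fruit_salad",
  "display_name": "fruit salad",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "yoghurt_and_granola",
  "display_name": "yoghurt and granola",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "scone_with_jam",
  "display_name": "scone with jam",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "carrot_cake",
  "display_name": "carrot cake",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "chocolate_brownie",
  "display_name": "chocolate brownie",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "apple_pie",
  "display_name": "apple pie",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "lemon_tart",
  "display_name": "lemon tart",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "raisin_toast",
  "display_name": "raisin toast",
  "category": "sweet_food",
  "is_filler": false
 },
 {
  "item_id": "banana_smoothie",
  "display_name": "banana smoothie",
  "category": "beverage",
  "is_filler": false,
  "recognition_meta": {
   "younger": 0.959,
   "older": 0.8
  }
 },
 {
  "item_id": "cranberry_juice",
  "display_name": "cranberry juice",
  "category": "beverage",
  "is_filler": true,
  "recognition_meta": {
   "overall": 0.451
  }
 },
 {
  "item_id": "flat_white",
  "display_name": "flat white",
  "category": "beverage",
  "is_filler": false
 },
 {
  "item_id": "cappuccino",
  "display_name": "cappuccino",
  "category": "beverage",
  "is_filler": false
 },
 {
  "item_id": "latte",
  "display_name": "latte",
  "category": "beverage",
  "is_filler": false
 },
 {
  "item_id": "english_breakfast_tea",
  "display_name": "english breakfast tea",
  "category": "beverage",
  "is_filler": false
 },
 {
  "item_id": "hot_chocolate",
  "display_name": "hot chocolate",
  "category": "beverage",
  "is_filler": false
 },
 {
  "item_id": "orange_juice",
  "display_name": "orange juice",
  "category": "beverage",
  "is_filler": false
 },
 {
  "item_id": "iced_coffee",
  "display_name": "iced coffee",
  "category": "beverage",
  "is_filler": false
 }
]
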