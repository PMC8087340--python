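# Default diet score table "default_v1".
#
# 51 food items, each assigned to one of 20 food groups and, through the
# group, to a consumption class:
#   daily      — recommended daily (dairy, fruit, vegetables, cereals, olive oil)
#   weekly     — recommended a few times per week (fish, meat, legumes, rice, nuts)
#   occasional — recommended only occasionally (processed/fried/sugary/alcohol)
# Penalty points per (class, frequency level) are 1-10, higher = less
# healthy at that frequency.  The roster and penalties are configuration:
# any table with the same shape can replace this file.
name: default_v1
penalties:
  daily:      {L0: 10, L1: 8, L2: 6, L3: 4, L4: 1, L5: 2}
  weekly:     {L0: 8,  L1: 5, L2: 2, L3: 1, L4: 4, L5: 7}
  occasional: {L0: 1,  L1: 2, L2: 4, L3: 6, L4: 8, L5: 10}
groups:
  milk:         {label: "Milk and derivatives",   class: daily}
  cheeses:      {label: "Cheeses",                class: weekly}
  meats:        {label: "Meats",                  class: weekly}
  sausage:      {label: "Sausage",                class: occasional}
  white_fish:   {label: "White fish",             class: weekly}
  blue_fish:    {label: "Blue fish",              class: weekly}
  seafood:      {label: "Seafood",                class: weekly}
  vegetables:   {label: "Vegetables",             class: daily}
  fruits:       {label: "Fruits",                 class: daily}
  legumes:      {label: "Legumes",                class: weekly}
  cereals:      {label: "Cereals and derivatives", class: daily}
  rice:         {label: "Rice",                   class: weekly}
  olive_oil:    {label: "Olive oil",              class: daily}
  other_oils:   {label: "Other oils",             class: occasional}
  butter:       {label: "Butter",                 class: occasional}
  french_fries: {label: "French fries",           class: occasional}
  sweetmeats:   {label: "Sweetmeats",             class: occasional}
  soft_drinks:  {label: "Soft drinks with sugar", class: occasional}
  alcohol:      {label: "Alcohol drinks",         class: occasional}
  nuts:         {label: "Nuts",                   class: weekly}
items:
  milk_whole: milk
  milk_skimmed: milk
  yogurt: milk
  dairy_desserts: milk
  cheese_fresh: cheeses
  cheese_cured: cheeses
  chicken: meats
  beef: meats
  pork: meats
  lamb: meats
  cured_sausage: sausage
  cooked_ham: sausage
  hake: white_fish
  other_white_fish: white_fish
  sardines: blue_fish
  tuna: blue_fish
  shellfish: seafood
  squid_octopus: seafood
  leafy_greens: vegetables
  tomatoes: vegetables
  root_vegetables: vegetables
  other_vegetables: vegetables
  citrus: fruits
  banana: fruits
  apple_pear: fruits
  other_fruit: fruits
  lentils: legumes
  chickpeas: legumes
  beans: legumes
  bread: cereals
  pasta: cereals
  breakfast_cereal: cereals
  other_cereals: cereals
  rice_dish: rice
  olive_oil_item: olive_oil
  sunflower_oil: other_oils
  margarine: other_oils
  butter_item: butter
  french_fries_item: french_fries
  crisps: french_fries
  pastries: sweetmeats
  cookies: sweetmeats
  chocolate: sweetmeats
  candy: sweetmeats
  cola_drinks: soft_drinks
  other_soft_drinks: soft_drinks
  beer: alcohol
  wine: alcohol
  spirits: alcohol
  nuts_item: nuts
  seeds: nuts
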