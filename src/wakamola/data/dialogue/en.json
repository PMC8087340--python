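{
 "language": "en",
 "menu": "Hello! I am Wakamola. Choose a section:",
 "reprompt": "Sorry, I did not understand that answer. Please try again.",
 "section_done": "Section already completed (add '!' to the menu choice to restart). Keep going with the other sections!",
 "diet_template": "How often do you eat {item}? Answer with a number: {levels}",
 "status_template": "Your Wakastatus is {wakastatus} out of 100.\nDiet: {diet} | Activity: {activity} | WakaBMI: {bmi_score} | Social: {social}\nYour BMI is {bmi} ({category}). The higher each score, the better your status!",
 "section_names": {
  "personal": "Personal",
  "diet": "Diet",
  "activity": "Physical activity",
  "wakanet": "Share Wakamola (Wakanet)",
  "wakastatus": "My status (Wakastatus)",
  "about": "Wakamola is a research tool to study diet, activity and social ties in a population. Your answers build your personal status score."
 },
 "levels": {
  "0": "never",
  "1": "less than once a week",
  "2": "1-2 times a week",
  "3": "3-6 times a week",
  "4": "once a day",
  "5": "twice a day or more"
 },
 "invite": {
  "home": "Join me on Wakamola! Invitation for the people I live with. Token: {token}",
  "family": "Join me on Wakamola! Invitation for my family. Token: {token}",
  "friend": "Join me on Wakamola! Invitation for my friends. Token: {token}",
  "work": "Join me on Wakamola! Invitation for my work contacts. Token: {token}"
 },
 "categories": {
  "underweight": "underweight",
  "normal": "normal weight",
  "overweight": "overweight",
  "obesity1": "obesity class 1",
  "obesity2": "obesity class 2",
  "obesity3": "obesity class 3"
 },
 "prompts": {
  "personal.weight": "What is your weight in kg?",
  "personal.height": "What is your height in metres?",
  "personal.gender": "What is your gender?",
  "personal.age": "How old are you?",
  "personal.education_level": "What is your highest education level?",
  "personal.marital_status": "What is your marital status?",
  "personal.household_size": "How many people live in your home, including you?",
  "personal.main_activity": "What is your main activity?",
  "personal.zip_code": "What is your postal code?",
  "personal.sleep_hours": "How many hours do you sleep per day?",
  "personal.cigarettes": "How many cigarettes do you smoke per day?",
  "personal.dx_hypertension": "Have you been diagnosed with, or do you take medication for, hypertension?",
  "personal.dx_diabetes": "Have you been diagnosed with, or do you take medication for, diabetes?",
  "personal.dx_cholesterol": "Have you been diagnosed with, or do you take medication for, high cholesterol?",
  "personal.dx_cardiovascular": "Have you been diagnosed with, or do you take medication for, cardiovascular disease?",
  "activity.vigorous_days": "On how many of the last 7 days did you do vigorous physical activity?",
  "activity.vigorous_minutes": "How many minutes of vigorous activity did you usually do on one of those days?",
  "activity.moderate_days": "On how many of the last 7 days did you do moderate physical activity?",
  "activity.moderate_minutes": "How many minutes of moderate activity did you usually do on one of those days?",
  "activity.walk_days": "On how many of the last 7 days did you walk for at least 10 continuous minutes?",
  "activity.walk_minutes": "How many minutes did you usually spend walking on one of those days?",
  "activity.sitting_hours": "How many hours per week do you spend sitting?"
 },
 "items": {
  "milk_whole": "whole milk",
  "milk_skimmed": "skimmed milk",
  "yogurt": "yogurt",
  "dairy_desserts": "dairy desserts",
  "cheese_fresh": "fresh cheese",
  "cheese_cured": "cured cheese",
  "chicken": "chicken",
  "beef": "beef",
  "pork": "pork",
  "lamb": "lamb",
  "cured_sausage": "cured sausage",
  "cooked_ham": "cooked ham",
  "hake": "hake",
  "other_white_fish": "other white fish",
  "sardines": "sardines",
  "tuna": "tuna",
  "shellfish": "shellfish",
  "squid_octopus": "squid or octopus",
  "leafy_greens": "leafy greens",
  "tomatoes": "tomatoes",
  "root_vegetables": "root vegetables",
  "other_vegetables": "other vegetables",
  "citrus": "citrus fruit",
  "banana": "banana",
  "apple_pear": "apple or pear",
  "other_fruit": "other fruit",
  "lentils": "lentils",
  "chickpeas": "chickpeas",
  "beans": "beans",
  "bread": "bread",
  "pasta": "pasta",
  "breakfast_cereal": "breakfast cereal",
  "other_cereals": "other cereals",
  "rice_dish": "rice",
  "olive_oil_item": "olive oil",
  "sunflower_oil": "sunflower oil",
  "margarine": "margarine",
  "butter_item": "butter",
  "french_fries_item": "french fries",
  "crisps": "crisps",
  "pastries": "pastries",
  "cookies": "cookies",
  "chocolate": "chocolate",
  "candy": "candy",
  "cola_drinks": "cola drinks",
  "other_soft_drinks": "other sugary soft drinks",
  "beer": "beer",
  "wine": "wine",
  "spirits": "spirits",
  "nuts_item": "nuts",
  "seeds": "seeds"
 }
}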