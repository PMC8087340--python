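{
 "language": "es",
 "menu": "¡Hola! Soy Wakamola. Elige una sección:",
 "reprompt": "Perdona, no he entendido esa respuesta. Inténtalo de nuevo.",
 "section_done": "Sección ya completada (añade '!' a la opción del menú para reiniciarla). ¡Sigue con las demás secciones!",
 "diet_template": "¿Con qué frecuencia comes {item}? Responde con un número: {levels}",
 "status_template": "Tu Wakastatus es {wakastatus} sobre 100.\nDieta: {diet} | Actividad: {activity} | WakaBMI: {bmi_score} | Social: {social}\nTu IMC es {bmi} ({category}). ¡Cuanto más alta cada puntuación, mejor tu estado!",
 "section_names": {
  "personal": "Personal",
  "diet": "Dieta",
  "activity": "Actividad física",
  "wakanet": "Comparte Wakamola (Wakanet)",
  "wakastatus": "Mi estado (Wakastatus)",
  "about": "Wakamola es una herramienta de investigación para estudiar dieta, actividad y relaciones sociales en una población. Tus respuestas construyen tu puntuación de estado."
 },
 "levels": {
  "0": "nunca",
  "1": "menos de una vez por semana",
  "2": "1-2 veces por semana",
  "3": "3-6 veces por semana",
  "4": "una vez al día",
  "5": "dos o más veces al día"
 },
 "invite": {
  "home": "¡Únete a Wakamola! Invitación para las personas con las que vivo. Token: {token}",
  "family": "¡Únete a Wakamola! Invitación para mi familia. Token: {token}",
  "friend": "¡Únete a Wakamola! Invitación para mis amistades. Token: {token}",
  "work": "¡Únete a Wakamola! Invitación para mis contactos del trabajo. Token: {token}"
 },
 "categories": {
  "underweight": "bajo peso",
  "normal": "peso normal",
  "overweight": "sobrepeso",
  "obesity1": "obesidad clase 1",
  "obesity2": "obesidad clase 2",
  "obesity3": "obesidad clase 3"
 },
 "prompts": {
  "personal.weight": "¿Cuál es tu peso en kg?",
  "personal.height": "¿Cuál es tu altura en metros?",
  "personal.gender": "¿Cuál es tu género?",
  "personal.age": "¿Cuántos años tienes?",
  "personal.education_level": "¿Cuál es tu nivel de estudios?",
  "personal.marital_status": "¿Cuál es tu estado civil?",
  "personal.household_size": "¿Cuántas personas viven en tu casa, contándote a ti?",
  "personal.main_activity": "¿Cuál es tu actividad principal?",
  "personal.zip_code": "¿Cuál es tu código postal?",
  "personal.sleep_hours": "¿Cuántas horas duermes al día?",
  "personal.cigarettes": "¿Cuántos cigarrillos fumas al día?",
  "personal.dx_hypertension": "¿Te han diagnosticado hipertensión o tomas medicación para ella?",
  "personal.dx_diabetes": "¿Te han diagnosticado diabetes o tomas medicación para ella?",
  "personal.dx_cholesterol": "¿Te han diagnosticado colesterol alto o tomas medicación para ello?",
  "personal.dx_cardiovascular": "¿Te han diagnosticado una enfermedad cardiovascular o tomas medicación para ella?",
  "activity.vigorous_days": "¿Cuántos de los últimos 7 días realizaste actividad física vigorosa?",
  "activity.vigorous_minutes": "¿Cuántos minutos de actividad vigorosa solías hacer en uno de esos días?",
  "activity.moderate_days": "¿Cuántos de los últimos 7 días realizaste actividad física moderada?",
  "activity.moderate_minutes": "¿Cuántos minutos de actividad moderada solías hacer en uno de esos días?",
  "activity.walk_days": "¿Cuántos de los últimos 7 días caminaste al menos 10 minutos seguidos?",
  "activity.walk_minutes": "¿Cuántos minutos solías caminar en uno de esos días?",
  "activity.sitting_hours": "¿Cuántas horas a la semana pasas sentado o sentada?"
 },
 "items": {
  "milk_whole": "leche entera",
  "milk_skimmed": "leche desnatada",
  "yogurt": "yogur",
  "dairy_desserts": "postres lácteos",
  "cheese_fresh": "queso fresco",
  "cheese_cured": "queso curado",
  "chicken": "pollo",
  "beef": "ternera",
  "pork": "cerdo",
  "lamb": "cordero",
  "cured_sausage": "embutido curado",
  "cooked_ham": "jamón cocido",
  "hake": "merluza",
  "other_white_fish": "otros pescados blancos",
  "sardines": "sardinas",
  "tuna": "atún",
  "shellfish": "marisco",
  "squid_octopus": "calamar o pulpo",
  "leafy_greens": "verduras de hoja",
  "tomatoes": "tomates",
  "root_vegetables": "hortalizas de raíz",
  "other_vegetables": "otras verduras",
  "citrus": "cítricos",
  "banana": "plátano",
  "apple_pear": "manzana o pera",
  "other_fruit": "otras frutas",
  "lentils": "lentejas",
  "chickpeas": "garbanzos",
  "beans": "alubias",
  "bread": "pan",
  "pasta": "pasta",
  "breakfast_cereal": "cereales de desayuno",
  "other_cereals": "otros cereales",
  "rice_dish": "arroz",
  "olive_oil_item": "aceite de oliva",
  "sunflower_oil": "aceite de girasol",
  "margarine": "margarina",
  "butter_item": "mantequilla",
  "french_fries_item": "patatas fritas",
  "crisps": "patatas de bolsa",
  "pastries": "bollería",
  "cookies": "galletas",
  "chocolate": "chocolate",
  "candy": "golosinas",
  "cola_drinks": "refrescos de cola",
  "other_soft_drinks": "otros refrescos azucarados",
  "beer": "cerveza",
  "wine": "vino",
  "spirits": "licores",
  "nuts_item": "frutos secos",
  "seeds": "semillas"
 }
}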