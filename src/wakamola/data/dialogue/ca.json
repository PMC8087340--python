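{
 "language": "ca",
 "menu": "Hola! Sóc Wakamola. Tria una secció:",
 "reprompt": "Perdona, no he entés eixa resposta. Torna-ho a intentar.",
 "section_done": "Secció ja completada (afig '!' a l'opció del menú per a reiniciar-la). Continua amb les altres seccions!",
 "diet_template": "Amb quina freqüència menges {item}? Respon amb un número: {levels}",
 "status_template": "El teu Wakastatus és {wakastatus} sobre 100.\nDieta: {diet} | Activitat: {activity} | WakaBMI: {bmi_score} | Social: {social}\nEl teu IMC és {bmi} ({category}). Com més alta cada puntuació, millor el teu estat!",
 "section_names": {
  "personal": "Personal",
  "diet": "Dieta",
  "activity": "Activitat física",
  "wakanet": "Comparteix Wakamola (Wakanet)",
  "wakastatus": "El meu estat (Wakastatus)",
  "about": "Wakamola és una eina de recerca per a estudiar dieta, activitat i relacions socials en una població. Les teues respostes construeixen la teua puntuació d'estat."
 },
 "levels": {
  "0": "mai",
  "1": "menys d'una vegada per setmana",
  "2": "1-2 vegades per setmana",
  "3": "3-6 vegades per setmana",
  "4": "una vegada al dia",
  "5": "dues o més vegades al dia"
 },
 "invite": {
  "home": "Uneix-te a Wakamola! Invitació per a les persones amb qui visc. Token: {token}",
  "family": "Uneix-te a Wakamola! Invitació per a la meua família. Token: {token}",
  "friend": "Uneix-te a Wakamola! Invitació per a les meues amistats. Token: {token}",
  "work": "Uneix-te a Wakamola! Invitació per als meus contactes del treball. Token: {token}"
 },
 "categories": {
  "underweight": "pes baix",
  "normal": "pes normal",
  "overweight": "sobrepés",
  "obesity1": "obesitat classe 1",
  "obesity2": "obesitat classe 2",
  "obesity3": "obesitat classe 3"
 },
 "prompts": {
  "personal.weight": "Quin és el teu pes en kg?",
  "personal.height": "Quina és la teua alçada en metres?",
  "personal.gender": "Quin és el teu gènere?",
  "personal.age": "Quants anys tens?",
  "personal.education_level": "Quin és el teu nivell d'estudis?",
  "personal.marital_status": "Quin és el teu estat civil?",
  "personal.household_size": "Quantes persones viuen a casa teua, comptant-te a tu?",
  "personal.main_activity": "Quina és la teua activitat principal?",
  "personal.zip_code": "Quin és el teu codi postal?",
  "personal.sleep_hours": "Quantes hores dorms al dia?",
  "personal.cigarettes": "Quantes cigarretes fumes al dia?",
  "personal.dx_hypertension": "T'han diagnosticat hipertensió o prens medicació per a ella?",
  "personal.dx_diabetes": "T'han diagnosticat diabetis o prens medicació per a ella?",
  "personal.dx_cholesterol": "T'han diagnosticat colesterol alt o prens medicació per a això?",
  "personal.dx_cardiovascular": "T'han diagnosticat una malaltia cardiovascular o prens medicació per a ella?",
  "activity.vigorous_days": "Quants dels últims 7 dies vas fer activitat física vigorosa?",
  "activity.vigorous_minutes": "Quants minuts d'activitat vigorosa solies fer en un d'aquests dies?",
  "activity.moderate_days": "Quants dels últims 7 dies vas fer activitat física moderada?",
  "activity.moderate_minutes": "Quants minuts d'activitat moderada solies fer en un d'aquests dies?",
  "activity.walk_days": "Quants dels últims 7 dies vas caminar almenys 10 minuts seguits?",
  "activity.walk_minutes": "Quants minuts solies caminar en un d'aquests dies?",
  "activity.sitting_hours": "Quantes hores a la setmana passes assegut o asseguda?"
 },
 "items": {
  "milk_whole": "llet sencera",
  "milk_skimmed": "llet desnatada",
  "yogurt": "iogurt",
  "dairy_desserts": "postres làctics",
  "cheese_fresh": "formatge fresc",
  "cheese_cured": "formatge curat",
  "chicken": "pollastre",
  "beef": "vedella",
  "pork": "porc",
  "lamb": "xai",
  "cured_sausage": "embotit curat",
  "cooked_ham": "pernil cuit",
  "hake": "lluç",
  "other_white_fish": "altres peixos blancs",
  "sardines": "sardines",
  "tuna": "tonyina",
  "shellfish": "marisc",
  "squid_octopus": "calamar o pop",
  "leafy_greens": "verdures de fulla",
  "tomatoes": "tomàquets",
  "root_vegetables": "hortalisses d'arrel",
  "other_vegetables": "altres verdures",
  "citrus": "cítrics",
  "banana": "plàtan",
  "apple_pear": "poma o pera",
  "other_fruit": "altres fruites",
  "lentils": "llenties",
  "chickpeas": "cigrons",
  "beans": "mongetes",
  "bread": "pa",
  "pasta": "pasta",
  "breakfast_cereal": "cereals d'esmorzar",
  "other_cereals": "altres cereals",
  "rice_dish": "arròs",
  "olive_oil_item": "oli d'oliva",
  "sunflower_oil": "oli de gira-sol",
  "margarine": "margarina",
  "butter_item": "mantega",
  "french_fries_item": "patates fregides",
  "crisps": "patates de bossa",
  "pastries": "brioixeria",
  "cookies": "galetes",
  "chocolate": "xocolata",
  "candy": "llaminadures",
  "cola_drinks": "refrescos de cola",
  "other_soft_drinks": "altres refrescos ensucrats",
  "beer": "cervesa",
  "wine": "vi",
  "spirits": "licors",
  "nuts_item": "fruita seca",
  "seeds": "llavors"
 }
}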