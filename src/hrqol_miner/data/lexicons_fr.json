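{
 "physical": [
  "douleur",
  "mal au dos",
  "nausées",
  "vertiges",
  "courbatures",
  "insomnies",
  "fatigue physique",
  "jambes lourdes",
  "maux de tête",
  "souffle court"
 ],
 "psychic": [
  "angoisse",
  "déprime",
  "idées noires",
  "moral à zéro",
  "crises de panique",
  "anxiété permanente",
  "stress constant",
  "envie de pleurer",
  "dépression"
 ],
 "activity": [
  "arrêt de travail",
  "impossible de sortir",
  "plus de sport",
  "activités quotidiennes limitées",
  "incapable de conduire",
  "journées à rester allongée",
  "mi-temps thérapeutique",
  "tâches ménagères impossibles"
 ],
 "relational": [
  "isolement",
  "disputes avec ma famille",
  "plus de vie sociale",
  "amis qui s'éloignent",
  "tensions dans le couple",
  "incompréhension de mes proches",
  "repli sur moi",
  "vie de famille compliquée"
 ],
 "financial": [
  "frais médicaux",
  "factures qui s'accumulent",
  "budget serré",
  "dépassements d'honoraires",
  "fins de mois difficiles",
  "soins non remboursés",
  "perte de revenus",
  "coût du traitement"
 ],
 "positive": [
  "content",
  "heureuse",
  "heureux",
  "soulagé",
  "soulagée",
  "agréable",
  "positif",
  "encourageant"
 ],
 "negative": [
  "horrible",
  "terrible",
  "pénible",
  "insupportable",
  "négatif",
  "affreux"
 ],
 "anger": [
  "colère",
  "énervé",
  "énervée",
  "furieux",
  "furieuse",
  "rage",
  "agacé"
 ],
 "disgust": [
  "dégoût",
  "dégoûté",
  "écoeuré",
  "écoeurée",
  "répugnant"
 ],
 "fear": [
  "peur",
  "effrayé",
  "effrayée",
  "terrifié",
  "inquiet",
  "inquiète",
  "crainte"
 ],
 "joy": [
  "joie",
  "ravi",
  "ravie",
  "sourire",
  "bonheur"
 ],
 "sadness": [
  "triste",
  "tristesse",
  "chagrin",
  "larmes",
  "pleurer"
 ],
 "surprise": [
  "surpris",
  "surprise",
  "étonné",
  "étonnée",
  "stupéfait",
  "inattendu"
 ]
}
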