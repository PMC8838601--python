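bonjour à tous sur ce forum.
merci d'avance pour vos réponses.
ce fil de discussion est très actif depuis quelques semaines.
la météo de cette semaine annonce enfin un peu de soleil.
le site a changé de présentation le mois dernier.
chacun partage ici son expérience à son rythme.
les réponses des autres membres sont souvent utiles.
cette rubrique regroupe des témoignages variés.
le prochain rendez-vous du groupe aura lieu au printemps.
un grand bonjour aux nouvelles personnes inscrites.
la modération garde ce sujet ouvert pour les questions.
bonne journée à toutes les personnes qui lisent ce message.
le village voisin organise un marché le dimanche matin.
les beaux jours reviennent doucement dans la région.
ce sujet a été déplacé depuis une autre rubrique.
des liens utiles sont rassemblés en première page.
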