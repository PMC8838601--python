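surface,canonical,category
levothyrox,levothyrox,drug
doliprane,doliprane,drug
ibuprofène,ibuprofène,drug
metformine,metformine,drug
sertraline,sertraline,drug
paracétamol,paracétamol,drug
tramadol,tramadol,drug
cortisone,cortisone,drug
diabète,diabète,disease
cancer,cancer,disease
endométriose,endométriose,disease
hypothyroïdie,hypothyroïdie,disease
asthme,asthme,disease
fibromyalgie,fibromyalgie,disease
sclérose en plaques,sclérose en plaques,disease
polyarthrite,polyarthrite,disease
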