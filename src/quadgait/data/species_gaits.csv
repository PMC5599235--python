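species,group,median_duty_factor,median_phase_pct,n,sd_duty_factor,sd_phase_pct
Hamster (Mesocricetus auratus),1,0.70,45,1,,
Giant Salamander (Andrias japonicus),1,0.74,40,1,,
Iguana (Iguana iguana),1,0.75,44,2,0.126,6.6
Komodo Dragon (Varanus komodoensis),1,0.77,45,3,0.031,1.7
Caiman (Caiman crocodilus),1,0.78,43,2,0.049,0.7
Hippo (Hippopotamus amphibius),1,0.76,45,4,0.082,2.1
Frog (Kassina maculata),1,0.78,44,1,,
Bearded Dragon (Pogona vitticeps),1,0.78,48,1,,
Crocodile (Crocodylus palustris),1,0.78,49,1,,
Leopard Gecko (Eublepharis macularius),1,0.79,43,2,0.034,3.5
Tiger Salamander (Ambystoma tigrinum),1,0.80,40,1,,
Monitor Lizard (Varanus salvator),1,0.81,40,1,,
Tortoise (Centrochelys sulcata),1,0.82,42,2,0.003,2.5
Iguana (Conolophus pallidus),1,0.84,47,1,,
Marine Iguana (Amblyrhynchus cristatus),1,0.85,41,1,,
Mouse (Mus musculus),1,0.86,40,1,,
Alligator (Alligator mississippiensis),1,0.87,42,3,0.046,2.7
Mongoose (Mungos mungo),2,0.60,16,2,0.046,2.8
Tapir (Tapirus indicus),2,0.61,26,1,,
Rat (Rattus norvegicus),2,0.62,36,1,,
Brown Bear (Ursus arctos),2,0.65,17,1,,
Hyena (Crocuta crocuta),2,0.66,10,1,,
Cat (Felis catus),2,0.66,21,2,0.060,3.7
Pig (Sus domesticus),2,0.66,26,1,,
Black Bear (Ursus americanus),2,0.67,18,1,,
Horse (Equus caballus),2,0.67,24,2,0.015,1.1
Zebra (Equus quagga),2,0.67,24,28,0.025,2.4
Echidna (Tachyglossus aculeatus),2,0.67,13,1,,
Polar Bear (Ursus maritimus),2,0.68,16,1,,
Rhino (Ceratotherium simum),2,0.68,21,2,0.079,1.7
Impala (Aepyceros melampus),2,0.68,19,1,,
Lion (Panthera leo),2,0.68,15,3,0.017,1.5
Sheep (Ovis aries),2,0.68,28,1,,
Giraffe (Giraffa camelopardalis),2,0.68,14,5,0.030,1.4
Cow (Bos taurus taurus),2,0.69,29,5,0.035,3.4
Deer (Odocoileus virginianus),2,0.69,31,2,0.049,9.1
Cheetah (Acinonyx jubatus),2,0.70,18,1,,
Giant Anteater (Myrmecophaga tridactyla),2,0.70,27,1,,
Tapir (Tapirus terrestris),2,0.70,26,1,,
American Buffalo (Bison bison),2,0.71,16,1,,
Bobcat (Lynx rufus),2,0.71,17,1,,
Barbary Sheep (Ammotragus lervia),2,0.71,26,1,,
Raccoon (Procyon lotor),2,0.71,14,1,,
Goat (Capra aegagrus hircus),2,0.72,23,1,,
Llama (Lama glama),2,0.72,17,1,,
Camel (Camelus bactrianus),2,0.72,21,1,,
Wildebeest (Connochaetes taurinus),2,0.72,18,11,0.017,1.6
Donkey (Equus africanus asinus),2,0.73,25,1,,
Elephant (Elephas maximus),2,0.73,19,1,,
Wombat (Lasiorhinus krefftii),2,0.73,18,1,,
Elephant (Loxodonta africana),2,0.74,17,4,0.026,1.3
Porcupine (Erethizon dorsatum),2,0.75,29,2,0.051,0
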