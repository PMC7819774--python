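item_label,scale_size,c1,c2,c3,c4,nominal_n,mean_printed,sd_printed,endorse_pct_printed
"The parents I work with have regular access to healthy foods.",4,7,25,39,3,74,2.5,0.7,
"The parents I work with and their families would benefit from learning more about how to eat healthy.",4,1,2,44,27,74,3.3,0.6,96
"I would be interested in learning how to deliver nutrition information to the parents I work with.",4,0,4,38,32,74,3.4,0.6,95
"Most of the parents I work with or their families would benefit from weight loss or better weight management.",4,1,25,28,20,74,2.9,0.8,
"I would be interested in learning how to deliver weight management information to the parents I work with.",4,5,20,25,24,74,2.9,0.9,
"The parents I work with and their families would benefit from learning more about healthy levels of physical activity and exercise.",4,0,6,43,25,74,3.3,0.6,92
"I would be interested in learning how to deliver information on physical activity to the parents I work with.",4,0,14,38,22,74,3.1,0.7,81
"The parents I work with would benefit from a home visiting program designed to improve the body weight and health of young children in the home.",4,1,14,40,17,72,3.0,0.7,79
"The parents I work with would benefit from mobile health tools designed to improve their diet, activity levels, body weight, and health.",4,0,14,42,18,74,3.1,0.7,
"I would be interested in receiving support via mobile health tools to help me deliver health and weight management information to the parents I work with and their families.",4,0,15,34,25,74,3.1,0.7,80
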