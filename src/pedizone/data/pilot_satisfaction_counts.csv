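group,item_label,scale_size,c1,c2,c3,c4,c5,c6,nominal_n,mean_printed,sd_printed
parent_program,"Seeing my child's weight on a graph every week helped me make better food choices for him/her.",6,0,0,3,3,1,3,10,4.4,1.2
parent_program,"My child was willing to step on the bathroom scale once per week.",6,0,0,0,2,0,8,10,5.6,0.8
parent_program,"My child was willing to wear a pedometer every day.",6,4,0,0,0,0,6,10,4.0,2.4
parent_program,"Tracking my child's steps each day helped him/her reach physical activity goals.",6,0,2,2,0,1,5,10,4.5,1.7
parent_program,"Tracking the foods my child ate helped him/her reach weight goals.",6,0,0,2,1,1,6,10,5.1,1.2
parent_program,"The healthy tips my child and I received helped me make healthy lifestyle changes for my child.",6,0,0,1,0,3,6,10,5.4,0.9
parent_program,"The information I received in my health tips helped me make healthy lifestyle changes for my family & myself.",6,0,0,0,2,3,5,10,5.3,0.8
parent_program,"I enjoyed the individual time talking with my counselor.",6,0,0,0,0,2,7,10,5.8,0.4
parent_program,"The amount of time talking with my interventionist was enough.",6,0,0,0,0,3,7,10,5.7,0.5
parent_program,"I would have liked to spend more time talking with my interventionist.",6,5,2,3,0,0,0,10,1.8,0.9
parent_program,"I enjoyed meeting with my counselor remotely (by phone call or video chat on my smartphone).",6,0,0,0,0,2,8,10,5.8,0.4
parent_helpfulness,"Learning about the importance of self-monitoring how much we eat and our activity.",6,0,0,0,0,3,7,10,5.7,0.5
parent_helpfulness,"Learning about portion control.",6,0,0,0,0,3,7,10,5.7,0.5
parent_helpfulness,"Learning about choosing the right foods for you and your child.",6,0,0,0,1,4,5,10,5.4,0.7
parent_helpfulness,"Learning about how to build good social support.",6,0,0,1,0,3,6,10,5.4,0.9
parent_helpfulness,"Learning about fat, protein, and carbohydrates.",6,0,0,0,0,5,5,10,5.5,0.5
parent_helpfulness,"Learning about how to overcome barriers to being healthy.",6,0,0,1,0,3,6,10,5.4,0.9
parent_helpfulness,"Learning about how to make better choices when eating outside the home.",6,0,0,0,0,3,7,10,5.7,0.5
parent_helpfulness,"Learning how to make healthy choices on special occasions such as birthday parties and school functions.",6,0,0,0,1,5,4,10,5.3,0.6
parent_helpfulness,"Learning about healthy eating plans for the whole family, like the Stoplight approach to healthy eating.",6,0,0,0,0,3,7,10,5.7,0.5
parent_helpfulness,"Learning about how much physical activity is recommended for me and my child.",6,0,0,0,0,5,5,10,5.5,0.5
parent_helpfulness,"Taking a closer look at why we eat.",6,0,0,0,1,5,4,10,5.3,0.6
parent_helpfulness,"Learning about healthy beverage choices for me and my child.",6,1,0,0,0,3,6,10,5.2,1.5
child,"I liked wearing my pedometer.",5,2,0,5,1,2,,10,3.1,0.4
child,"I liked seeing how many steps I can get each day.",5,0,1,1,2,8,,10,4.3,0.3
child,"The pedometer was easy to use.",5,1,2,1,3,3,,10,3.5,0.5
child,"I tried to move more.",5,2,0,2,3,3,,10,3.5,0.5
child,"I liked talking to my counselor about eating healthy foods and being more active.",5,1,0,2,2,5,,10,4.0,0.4
child,"I tried to eat healthier foods.",5,1,0,2,1,6,,10,4.1,0.4
child,"I tried new healthy foods that I had not tried before.",5,1,1,2,1,5,,10,3.8,0.5
child,"I ate less candy.",5,2,2,1,1,4,,10,3.3,0.5
child,"I drank less soda.",5,1,1,2,2,4,,10,3.7,0.5
child,"I talked with my parents about eating healthier foods.",5,3,1,3,2,1,,10,2.7,0.5
child,"Getting on the scale once a week was easy.",5,1,0,1,2,6,,10,4.2,0.4
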