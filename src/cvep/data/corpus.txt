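HOW DO YOU LIKE THE PASTA YOU EAT
I WANT SOMETHING TO DRINK
COULD YOU PREPARE SOME HOT CHOCOLATE
MY MOTHER BAKES REALLY NICE CAKES
THE WEATHER IN GERMANY IS MOSTLY COLD
WE WILL MAKE A STUDY ROUND TOMORROW
YOU SPEAK ENGLISH VERY WELL
WHAT DO YOU DO FOR WORK
NEXT TIME WE WILL ORDER THE BIG BURGER
WE WILL GO ON HOLYDAYS NEXT MONTH
I WOULD LIKE TO EAT SOMETHING
ONE APPLE A DAY MAKES THE DOCTOR AWAY
I TAKE YOGA AND PILATES CLASSES
WOULD YOU MIND IF I GO EARLIER TONIGHT
AT NIGHT OR IN THE MORNING
WE LIVE IN THE BEST OF ALL POSSIBLE WORLDS
I WOULD LIKE SOME COFFEE
YOU CANNOT STEP TWICE IN THE SAME RIVER
WHAT ARE YOU GOING TO DO TODAY
LIBERTY CONSISTS IN DOING WHAT ONE DESIRES
I WILL TRY TO MAKE IT RIGHT THIS TIME
HOW ABOUT THE KOREAN RESTAURANT
WHAT ARE YOU PLANNING TO DO TODAY
WE MUST TAKE CARE OF OUR PLANET
PLEASE BRING ALL YOUR DOCUMENTS BY TOMORROW
I NEED TO GO TO THE STORE TOO
DO YOU FEEL COMFORTABLE ON THAT CHAIR
I AM ONLY HAPPY WHEN IT RAINS
HAVING A HEALTHY LIFE IS IMPORTANT
THE SCIENCE OF TODAY IS THE TECHNOLOGY OF TOMORROW
MAN IS THE MEASURE OF ALL THINGS
WOULD YOU LIKE TO GO NOW OR LATER
I WOULD LIKE TO COME WITH YOU
LEARNING IS THE BEGINNING OF WEALTH
ALWAYS GO WHERE THE PEOPLE DANCE
DO NOT JUDGE MY PAST I DO NOT LIVE THERE
IT IS NEVER GOOD TO BE CRUEL WITH OTHERS
USE WHAT YOU HAVE AND DO WHAT YOU CAN
NOTHING REALLY SEEMS TO BE EASY
YESTERDAY I FOUND MONEY IN MY PANTS
KNOWING IS NOT ENOUGH WE MUST APPLY
YOU ARE NEVER TOO OLD TO SET ANOTHER GOAL
YOU SHOULD BE DANCING SALSA NOW
WOULD YOU GO TO THE CINEMA WITH ME
SET YOUR GOALS HIGH AND NEVER STOP
PROBLEMS ARE NOT STOP SIGNS THEY ARE GUIDELINES
IT ALWAYS SEEMS IMPOSSIBLE TILL IT IS DONE
MUSIC IS MOTIVATIONAL AND MAKES YOU RELAX
TO SUCCEED YOU MUST FIRST BELIEVE
FOLLOW YOUR INNER MOONLIGHT AND DO NOT HIDE
BE GENTLE WITH ALL AND STERN WITH YOURSELF
MAY THE FORCE BE WITH YOU ON MONDAY
SHE LIKES CHOCOLATE ICE CREAM
THE BANANAS HERE DO NOT TASTE DELICIOUS
THE WINTER TIME IS REALLY COLD AND HUMID
I WILL MAKE HIM AN OFFER HE CAN NOT REFUSE
MY NAME IS BOND JUST BOND
I WOULD LIKE TO GET SOME SUNSHINE EVERYDAY
THE QUICK BROWN FOX JUMPS OVER THE LAZY DOG
GOOD MORNING HOW ARE YOU TODAY
I AM FINE THANK YOU VERY MUCH
THE SUN IS SHINING THIS MORNING
PLEASE OPEN THE WINDOW A LITTLE
CAN YOU HEAR ME WELL FROM THERE
THE CAT SLEEPS ON THE WARM SOFA
MY BROTHER PLAYS FOOTBALL EVERY SUNDAY
SHE READS A NEW BOOK EVERY WEEK
THE TRAIN LEAVES IN TEN MINUTES
WE SHOULD VISIT OUR GRANDMOTHER SOON
THE COFFEE IS TOO HOT TO DRINK
HE WORKS IN A SMALL OFFICE DOWNTOWN
THE CHILDREN PLAY IN THE GARDEN
I FORGOT MY KEYS AT HOME AGAIN
THE MOVIE STARTS AT EIGHT TONIGHT
PLEASE PASS ME THE SALT AND PEPPER
THE DOG BARKS AT THE POSTMAN
WE WALKED ALONG THE RIVER YESTERDAY
THE SHOP CLOSES EARLY ON SATURDAY
I WILL CALL YOU BACK IN A MINUTE
THE ROOM IS CLEAN AND BRIGHT
SHE SINGS IN THE SCHOOL CHOIR
THE BREAD SMELLS FRESH AND WARM
HE DRIVES TO WORK EVERY MORNING
THE STARS ARE BRIGHT TONIGHT
I LIKE TO READ BEFORE SLEEPING
THE WATER IN THE LAKE IS COLD
WE MET OUR FRIENDS AT THE PARK
THE TEACHER EXPLAINS THE LESSON SLOWLY
MY FAVOURITE COLOUR IS DEEP BLUE
THE BIRDS SING EARLY IN THE MORNING
PLEASE TURN OFF THE LIGHT WHEN YOU LEAVE
I BOUGHT FRESH FRUIT AT THE MARKET
THE SOUP NEEDS A LITTLE MORE SALT
HE LOST HIS WALLET ON THE BUS
THE GAME WAS EXCITING UNTIL THE END
SHE PAINTS SMALL PICTURES OF FLOWERS
WE SHOULD LEAVE BEFORE THE RAIN STARTS
THE LIBRARY IS QUIET IN THE AFTERNOON
I WILL MAKE DINNER FOR US TONIGHT
THE STREETS ARE EMPTY AT NIGHT
MY SISTER STUDIES MEDICINE IN BERLIN
THE CAKE TASTES LIKE LEMON AND HONEY
HE RUNS FIVE MILES EVERY EVENING
THE ANSWER TO YOUR QUESTION IS SIMPLE
WE WATCHED THE SUNSET FROM THE HILL
THE LETTER ARRIVED THIS MORNING
PLEASE CLOSE THE DOOR QUIETLY
I WOULD LIKE TO LEARN TO PLAY PIANO
THE GARDEN IS FULL OF RED ROSES
SHE SPEAKS THREE LANGUAGES FLUENTLY
THE BRIDGE CROSSES THE OLD CANAL
WE WILL MEET AGAIN NEXT FRIDAY
THE CLOCK ON THE WALL IS SLOW
HE WEARS A BLUE COAT IN WINTER
THE STORY ENDS WITH A SURPRISE
I NEED A NEW PAIR OF SHOES
THE KITCHEN SMELLS OF FRESH COFFEE
MY FRIEND LIVES NEAR THE STATION
THE WIND BLOWS STRONG FROM THE SEA
PLEASE WRITE YOUR NAME ON THE LIST
I WILL TRY TO COME EARLIER TOMORROW
THE MUSIC WAS TOO LOUD AT THE PARTY
SHE FOUND A COIN UNDER THE TABLE
WE LIKE TO SWIM IN THE SUMMER
THE MOUNTAIN ROAD IS NARROW AND STEEP
HE TELLS THE SAME JOKE EVERY TIME
THE MILK IS IN THE FRIDGE
I LIKE THE QUIET OF THE EARLY MORNING
THE BOAT SAILS SLOWLY DOWN THE RIVER
WE PLANTED A SMALL TREE IN THE YARD
THE PHONE RANG THREE TIMES
SHE SMILED AND WAVED FROM THE TRAIN
THE SNOW COVERED THE WHOLE TOWN
I WILL WAIT FOR YOU AT THE CORNER
THE MEETING WAS SHORT AND USEFUL
HE FIXED THE OLD CLOCK IN AN HOUR
THE APPLES ARE SWEET THIS YEAR
WE TALKED UNTIL LATE IN THE NIGHT
THE PATH LEADS THROUGH THE FOREST
PLEASE BRING YOUR OWN CUP TO THE PARTY
I LIKE TO DRINK TEA WITH HONEY
THE CITY LOOKS BEAUTIFUL AT NIGHT
SHE KEEPS HER NOTES IN A GREEN BOX
WE WILL PAINT THE FENCE NEXT WEEK
THE CHILD DREW A HOUSE AND A TREE
HE ALWAYS LOCKS THE DOOR TWICE
THE TEA IS READY ON THE TABLE
I HEARD A NICE SONG ON THE RADIO
THE GRASS IS GREEN AFTER THE RAIN
WE NEED MORE CHAIRS FOR THE GUESTS
THE SHOP SELLS BREAD AND CHEESE
SHE CLOSED THE BOOK AND SLEPT
THE ROAD TO THE VILLAGE IS LONG
I WILL SEND YOU THE PHOTOS TONIGHT
THE FIRE KEPT US WARM ALL EVENING
HE COUNTS THE DAYS UNTIL SUMMER
THE DOOR OPENS WITH A SMALL KEY
WE ATE FRESH FISH BY THE HARBOUR
THE LAMP GIVES A SOFT YELLOW LIGHT
PLEASE CHECK THE TIME OF THE TRAIN
I LEFT A NOTE ON YOUR DESK
THE GARDEN GATE WAS OPEN AGAIN
SHE LEARNED TO RIDE A BIKE QUICKLY
WE HEARD THE BELLS FROM THE CHURCH
THE WINTER NIGHTS ARE LONG AND DARK
HE PUT THE LETTERS IN THE DRAWER
THE JUICE IS MADE FROM FRESH ORANGES
I ENJOY LONG WALKS ON THE BEACH
THE HOUSE AT THE CORNER IS FOR SALE
WE WILL VISIT THE MUSEUM ON SUNDAY
THE BABY SLEPT THROUGH THE WHOLE NIGHT
SHE WROTE HER NAME IN THE SAND
THE SOUP IS WARM AND THE BREAD IS FRESH
I WILL READ ONE MORE CHAPTER TONIGHT
THE KEYS ARE HANGING BY THE DOOR
WE SANG OLD SONGS AROUND THE FIRE
THE MORNING TRAIN IS ALWAYS FULL
HE GAVE THE RIGHT ANSWER AT ONCE
THE FLOWERS NEED WATER EVERY DAY
I LIKE THE SOUND OF FALLING RAIN
THE BRIDGE IS CLOSED FOR REPAIRS
WE FOUND A QUIET PLACE TO READ
THE EVENING SKY TURNED DEEP RED
SHE BRINGS FRESH FLOWERS EVERY FRIDAY
THE ANSWER CAME FASTER THAN EXPECTED
I WILL LEAVE THE DOOR UNLOCKED FOR YOU
THE TOWN SQUARE IS BUSY AT NOON
WE LISTENED TO THE WAVES FOR HOURS
THE LAST BUS LEAVES AT MIDNIGHT
HE KEEPS HIS TOOLS IN THE SHED
THE WINDOW LOOKS OUT ON THE GARDEN
I FOUND THE RECIPE IN AN OLD BOOK
THE CANDLES BURNED LOW AND WARM
WE CROSSED THE FIELD BEFORE DARK
THE FIRST SNOW FELL LAST NIGHT
SHE SAVED A SEAT FOR ME BY THE WINDOW
THE KETTLE WHISTLES IN THE KITCHEN
I WILL THINK ABOUT IT OVER THE WEEKEND
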