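; Starter education vocabulary (run input in production; bundled for tests
; and the synthetic generator).
education
school
schools
university
universities
college
colleges
student
students
teacher
teachers
professor
classroom
curriculum
homework
exam
exams
tuition
scholarship
degree
diploma
graduate
graduation
kindergarten
preschool
campus
lecture
semester
syllabus
textbook
learning
e-learning
online class
literacy
enrollment
academic
faculty
phd
undergraduate
tutoring
grading
dissertation
seminar
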